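"""Helical and cyclic symmetry: lattice generation, recovery, and detection.

A capsid-like helical lattice is described by screw parameters: an axial
``rise`` (Å) and ``twist`` (degrees) per asymmetric unit along the helical
axis, a ``start`` number (parallel helical strands forming a ring), and an
optional cyclic point symmetry. Handedness convention: positive twist
advances counter-clockwise when viewed down the +axis while rising along
+axis, i.e. a right-handed screw.

The estimator inverts the construction: superpose designated adjacent
units, decompose the resulting rigid transform into its screw parameters,
and infer the start number from the in-ring angle. Rotational symmetry of a
density map is detected by angular self-correlation about the axis.
"""

from __future__ import annotations

import dataclasses
import string

import numpy as np
from scipy.ndimage import map_coordinates

from .rigid import Pose, kabsch, rotation_about_axis, screw_decompose
from .structio import AtomicModel, DensityMap

__all__ = [
    "HelicalParams",
    "apply_helical",
    "apply_cn",
    "estimate_helical_params",
    "detect_rotational_order",
    "rotational_correlation_table",
    "AmbiguousLatticeError",
    "NoSymmetrySignalError",
]


class AmbiguousLatticeError(RuntimeError):
    """Adjacent units superpose too poorly to define a lattice transform."""


class NoSymmetrySignalError(RuntimeError):
    """The map shows no discriminating rotational-correlation structure."""


@dataclasses.dataclass
class HelicalParams:
    """Screw parameters of a helical assembly (per asymmetric unit)."""

    rise: float  # Å
    twist: float  # degrees, signed; positive = right-handed
    start: int = 1
    point_symmetry: int = 1
    axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180] degrees")
        if self.start < 1 or self.point_symmetry < 1:
            raise ValueError("start number and point symmetry must be >= 1")
        self.axis = np.asarray(self.axis, float).reshape(3)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be a non-zero vector")
        self.axis = self.axis / n
        self.axis_point = np.asarray(self.axis_point, float).reshape(3)


def _screw_pose(axis: np.ndarray, point: np.ndarray, angle_deg: float,
                rise: float) -> Pose:
    R = rotation_about_axis(axis, angle_deg)
    t = point - R @ point + rise * axis
    return Pose(R, t)


_CHAIN_LETTERS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _relabel(model: AtomicModel, copy_index: int) -> AtomicModel:
    out = model.copy()
    if copy_index == 0:
        return out
    suffix = _CHAIN_LETTERS[copy_index % len(_CHAIN_LETTERS)] \
        if copy_index < len(_CHAIN_LETTERS) else str(copy_index)
    out.chain = np.array([f"{c}{suffix}" for c in model.chain], dtype=object)
    return out


def apply_helical(unit: AtomicModel, params: HelicalParams,
                  n_rings: int) -> AtomicModel:
    """Expand one asymmetric unit into ``start x n_rings`` copies.

    Within a ring, copies are related by 360/start-degree rotations about
    the axis; successive rings by the (twist, rise) screw. Chains are
    relabelled deterministically (copy-index suffix); copy k of ring j gets
    index ``j*start + k``.
    """
    if unit.is_empty:
        raise ValueError("empty asymmetric unit")
    if n_rings < 1:
        raise ValueError("need at least one ring")
    copies = []
    for j in range(n_rings):
        screw = _screw_pose(params.axis, params.axis_point,
                            j * params.twist, j * params.rise)
        for k in range(params.start):
            ring_rot = _screw_pose(params.axis, params.axis_point,
                                   k * 360.0 / params.start, 0.0)
            pose = screw.compose(ring_rot)
            copies.append(_relabel(unit, j * params.start + k)
                          .transformed(pose.rotation, pose.translation))
    return AtomicModel.concatenate(copies)


def apply_cn(unit: AtomicModel, order: int,
             axis: np.ndarray = (0.0, 0.0, 1.0),
             axis_point: np.ndarray = (0.0, 0.0, 0.0)) -> AtomicModel:
    """Cyclic (Cn) expansion: ``order`` copies at multiples of 360/order."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if unit.is_empty:
        raise ValueError("empty unit")
    axis = np.asarray(axis, float)
    axis_point = np.asarray(axis_point, float)
    copies = []
    for k in range(order):
        pose = _screw_pose(axis, axis_point, k * 360.0 / order, 0.0)
        copies.append(_relabel(unit, k).transformed(pose.rotation, pose.translation))
    return AtomicModel.concatenate(copies)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def _chain_subset(assembly: AtomicModel, chains: list[str]) -> AtomicModel:
    sel = np.isin(assembly.chain.astype(str), chains)
    if not sel.any():
        raise ValueError(f"no atoms in chains {chains}")
    return assembly.select(sel)


def estimate_helical_params(assembly: AtomicModel,
                            unit_chains: list[str],
                            axial_neighbor_chains: list[str] | list[list[str]],
                            ring_neighbor_chains: list[str] | None = None,
                            rmsd_cutoff: float = 2.0) -> HelicalParams:
    """Recover screw parameters from an assembly of repeated units.

    ``unit_chains`` name the chains of one asymmetric unit;
    ``axial_neighbor_chains`` its partner one ring up (the screw-related
    copy) — or a *series* of consecutive axial copies (list of chain
    groups), in which case the screw parameters are averaged over the
    consecutive pairs, which beats single-pair estimation on noisy
    coordinates. ``ring_neighbor_chains``, when given, is the adjacent
    copy within the same ring, from which the start number is inferred as
    ``round(360 / ring angle)``. Units are superposed by least squares
    (atom order must correspond); an RMSD above ``rmsd_cutoff`` raises
    :class:`AmbiguousLatticeError`.
    """
    unit = _chain_subset(assembly, unit_chains)
    if axial_neighbor_chains and isinstance(axial_neighbor_chains[0], list):
        series: list[list[str]] = [unit_chains, *axial_neighbor_chains]  # type: ignore[list-item]
    else:
        series = [unit_chains, axial_neighbor_chains]  # type: ignore[list-item]
    axes, points, angles, rises = [], [], [], []
    for lower_chains, upper_chains in zip(series, series[1:]):
        lower = _chain_subset(assembly, lower_chains)
        upper = _chain_subset(assembly, upper_chains)
        if lower.n_atoms != upper.n_atoms:
            raise ValueError("unit copies have different atom counts")
        pose, rmsd = kabsch(lower.xyz, upper.xyz)
        if rmsd > rmsd_cutoff:
            raise AmbiguousLatticeError(
                f"unit superposition RMSD {rmsd:.2f} Å exceeds {rmsd_cutoff} Å")
        axis, point, angle, rise = screw_decompose(pose)
        twist = angle
        if rise < 0:
            axis, rise, twist = -axis, -rise, -twist
        axes.append(axis)
        points.append(point)
        angles.append(twist)
        rises.append(rise)
    axis = np.mean(axes, axis=0)
    axis = axis / np.linalg.norm(axis)
    point = np.mean(points, axis=0)
    rise = float(np.mean(rises))
    twist = float(np.mean(angles))
    if twist <= -180.0:
        twist += 360.0
    start = 1
    if ring_neighbor_chains is not None:
        ring = _chain_subset(assembly, ring_neighbor_chains)
        rpose, rrmsd = kabsch(unit.xyz, ring.xyz)
        if rrmsd > rmsd_cutoff:
            raise AmbiguousLatticeError(
                f"ring superposition RMSD {rrmsd:.2f} Å exceeds {rmsd_cutoff} Å")
        _, _, ring_angle, ring_rise = screw_decompose(rpose)
        if abs(ring_angle) < 1e-9:
            raise AmbiguousLatticeError("ring neighbour is a pure translation")
        start = max(1, int(round(360.0 / abs(ring_angle))))
    return HelicalParams(rise=float(rise), twist=float(twist), start=start,
                         axis=axis, axis_point=point)


# ---------------------------------------------------------------------------
# Rotational-order detection
# ---------------------------------------------------------------------------

def _principal_axis(dmap: DensityMap, threshold_sigmas: float = 1.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Inertia-tensor principal axis of thresholded density (axis, centre)."""
    g = dmap.grid.astype(np.float64)
    thr = g.mean() + threshold_sigmas * g.std()
    sel = g > thr
    if not sel.any():
        sel = g > g.mean()
    idx = np.argwhere(sel).astype(float)
    w = g[sel]
    w = w / w.sum()
    com = (idx * w[:, None]).sum(axis=0)
    d = (idx - com) * dmap.voxel
    cov = (d * w[:, None]).T @ d
    vals, vecs = np.linalg.eigh(cov)
    # a Cn-symmetric object has two (near-)degenerate inertia eigenvalues;
    # the symmetry axis belongs to the odd one out (works for both prolate
    # cylinders and flat rings)
    seps = [min(abs(vals[i] - vals[j]) for j in range(3) if j != i)
            for i in range(3)]
    axis = vecs[:, int(np.argmax(seps))]
    return axis, dmap.voxel_to_world(com)


def _rotated_grid(dmap: DensityMap, axis: np.ndarray, center: np.ndarray,
                  angle_deg: float) -> np.ndarray:
    R = rotation_about_axis(axis, angle_deg)
    shape = dmap.grid.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx * dmap.voxel + dmap.origin
    # sample the original map at the pre-image of each voxel
    src = (world - center) @ R + center  # R^T applied on the right
    src_vox = (src - dmap.origin) / dmap.voxel
    vals = map_coordinates(dmap.grid.astype(np.float64), src_vox.T, order=1,
                           mode="constant", cval=0.0)
    return vals.reshape(shape)


def rotational_correlation_table(dmap: DensityMap, orders: range,
                                 axis: np.ndarray | None = None,
                                 center: np.ndarray | None = None,
                                 max_angles_per_order: int = 3,
                                 ) -> dict[int, float]:
    """Mean self-correlation of the map under each candidate Cn rotation.

    For order n the map is rotated by k*360/n (k up to
    ``max_angles_per_order``) and correlated with itself over voxels with
    significant density in either copy; the per-order score is the mean.
    """
    if axis is None or center is None:
        est_axis, est_center = _principal_axis(dmap)
        axis = est_axis if axis is None else np.asarray(axis, float)
        center = est_center if center is None else np.asarray(center, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    g = dmap.grid.astype(np.float64)
    level = 0.1 * g.max() if g.max() > 0 else 0.0
    table: dict[int, float] = {}
    for n in orders:
        ccs = []
        ks = range(1, min(n - 1, max_angles_per_order) + 1) if n > 1 else [0]
        for k in ks:
            rot = _rotated_grid(dmap, axis, np.asarray(center, float),
                                k * 360.0 / n)
            sel = (g > level) | (rot > level)
            if not sel.any():
                ccs.append(0.0)
                continue
            a = g[sel] - g[sel].mean()
            b = rot[sel] - rot[sel].mean()
            denom = np.sqrt((a @ a) * (b @ b))
            ccs.append(float(a @ b / denom) if denom > 0 else 0.0)
        table[n] = float(np.mean(ccs))
    return table


def detect_rotational_order(dmap: DensityMap, orders: range = range(2, 17),
                            axis: np.ndarray | None = None,
                            center: np.ndarray | None = None,
                            tolerance: float = 0.05) -> int:
    """Detect the cyclic symmetry order of a map about an axis.

    Scores every candidate order by rotational self-correlation and returns
    the *largest* order within ``tolerance`` of the best score (a Cn map is
    also self-correlated at every divisor of n). If all tested orders score
    within tolerance of each other the map is rotationally degenerate
    (e.g. a spherical blob) and :class:`NoSymmetrySignalError` is raised.
    A flat map raises the same error.
    """
    g = dmap.grid
    if float(g.std()) == 0.0:
        raise NoSymmetrySignalError("flat map: no density contrast")
    table = rotational_correlation_table(dmap, orders, axis=axis, center=center)
    best = max(table.values())
    worst = min(table.values())
    if best - worst < tolerance:
        raise NoSymmetrySignalError(
            f"all orders score within {tolerance} of each other "
            f"(range {worst:.3f}..{best:.3f}); no rotational signal")
    return max(n for n, cc in table.items() if cc >= best - tolerance)
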