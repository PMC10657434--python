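"""Exhaustive rigid-body docking of candidates into sub-maps.

Rotations are enumerated on a deterministic quasi-uniform SO(3) grid; for
each rotation the best translation is found by (circular) FFT
cross-correlation of a simulated template against the sub-map, which is
numerically identical to scanning every voxel shift in real space. Peak
poses are re-scored with a masked Pearson map-to-model correlation
coefficient (CC), deduplicated by coordinate RMSD, and ranked; an optional
local simplex refinement polishes the top poses off the search grids.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .pool import Candidate
from .rigid import Pose
from .structio import AtomicModel, DensityMap
from .voldens import SubMap, lowpass, simulate_map

__all__ = [
    "DockParams",
    "FitResult",
    "rotation_grid",
    "cc_score",
    "translation_search",
    "exhaustive_dock",
    "refine_pose",
    "per_residue_cc",
    "fit_table",
]

NO_OVERLAP_CC = -1.0  # sentinel keeping rankings total when a pose misses the map


@dataclasses.dataclass(frozen=True)
class DockParams:
    """Knobs of the exhaustive search.

    ``angular_step`` controls the SO(3) grid spacing (degrees);
    ``scoring_resolution`` is the resolution the template is simulated at
    (defaults to the sub-map's nominal resolution); ``mask_mode`` chooses
    whether CC is computed over the voxels the model occupies
    (``model-mask``, map-to-model CC semantics) or over the whole sub-map
    mask; ``dedup_rmsd`` collapses search hits whose placed coordinates
    agree within that RMSD; ``refine`` enables off-grid pose polishing.
    """

    angular_step: float = 12.0
    top_n: int = 10
    scoring_resolution: float | None = None
    mask_mode: str = "model-mask"
    dedup_rmsd: float = 3.0
    refine: bool = False
    lowpass_template: bool = False  # filter-match templates to the map
    local_search_top: int = 16  # coarse orientations refined on a local grid
    model_mask_level: float = 0.1  # fraction of template max defining the mask

    def __post_init__(self) -> None:
        if not (0 < self.angular_step <= 180):
            raise ValueError("angular step must be in (0, 180] degrees")
        if self.top_n < 1:
            raise ValueError("top N must be >= 1")
        if self.mask_mode not in ("model-mask", "submap-mask"):
            raise ValueError(f"unknown mask mode {self.mask_mode!r}")


@dataclasses.dataclass
class FitResult:
    """One ranked rigid placement of a candidate in a sub-map."""

    candidate_id: str
    submap_label: str
    pose: Pose
    cc: float
    rank: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.cc):
            raise ValueError("CC must be finite")


def fit_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Fit results as a flat table (pose as 12 row-major floats)."""
    rows = []
    for f in fits:
        row = {"candidate": f.candidate_id, "source": f.source_id,
               "submap": f.submap_label, "rank": f.rank, "cc": f.cc}
        row.update({f"pose{i:02d}": v for i, v in enumerate(f.pose.as_flat())})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rotation sampling
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _rotation_grid_cached(angular_step: float) -> tuple[np.ndarray, ...]:
    """Deterministic quasi-uniform SO(3) grid with the given spacing (deg).

    Uses a ZYZ Euler grid uniform in (alpha, cos beta, gamma) — the Haar
    measure factorisation — so cells carry approximately equal weight. The
    identity rotation is always included; the gimbal-degenerate poles
    (beta = 0 or 180) keep a single alpha sweep.
    """
    if not (0 < angular_step <= 180):
        raise ValueError("angular step must be in (0, 180] degrees")
    n_inplane = max(1, int(round(360.0 / angular_step)))
    alphas = np.arange(n_inplane) * (360.0 / n_inplane)
    n_beta = max(2, int(round(180.0 / angular_step)) + 1)
    cos_betas = np.linspace(1.0, -1.0, n_beta)
    rots: list[np.ndarray] = []
    for cb in cos_betas:
        beta = np.rad2deg(np.arccos(np.clip(cb, -1, 1)))
        degenerate = beta < 1e-9 or beta > 180 - 1e-9
        for alpha in alphas:
            gammas = [0.0] if degenerate else alphas
            for gamma in gammas:
                rots.append(Rotation.from_euler(
                    "ZYZ", [alpha, beta, gamma], degrees=True).as_matrix())
    return tuple(rots)


def rotation_grid(angular_step: float) -> list[np.ndarray]:
    """Cached wrapper around the deterministic SO(3) grid construction."""
    return list(_rotation_grid_cached(float(angular_step)))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _experimental(map_or_submap: DensityMap | SubMap) -> tuple[DensityMap, np.ndarray | None]:
    if isinstance(map_or_submap, SubMap):
        return map_or_submap.masked_map(), map_or_submap.mask
    return map_or_submap, None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return NO_OVERLAP_CC
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def cc_score(map_or_submap: DensityMap | SubMap, model: AtomicModel, pose: Pose,
             params: DockParams = DockParams()) -> float:
    """Masked Pearson CC between the map and the simulated posed model.

    With ``model-mask`` (default) the correlation runs over the voxels
    where the simulated model has significant density — map-to-model CC
    semantics. Poses that miss the map entirely score the sentinel -1 so
    rankings stay total.
    """
    exp_map, submask = _experimental(map_or_submap)
    posed = model.transformed(pose.rotation, pose.translation)
    resolution = params.scoring_resolution or exp_map.resolution
    if resolution is None:
        raise ValueError("no scoring resolution: set DockParams.scoring_resolution "
                         "or the map's nominal resolution")
    sim = simulate_map(posed, resolution, like=exp_map)
    if params.lowpass_template:
        sim = lowpass(sim, resolution)
    peak = float(sim.grid.max())
    if peak <= 0:
        warnings.warn("posed model does not overlap the map; scoring -1")
        return NO_OVERLAP_CC
    if params.mask_mode == "model-mask":
        mask = sim.grid >= params.model_mask_level * peak
    else:
        mask = submask if submask is not None else np.ones(exp_map.grid.shape, bool)
    if not mask.any():
        warnings.warn("empty scoring mask; scoring -1")
        return NO_OVERLAP_CC
    return _pearson(exp_map.grid[mask], sim.grid[mask])


def model_coverage(map_or_submap: DensityMap | SubMap, model: AtomicModel,
                   pose: Pose) -> float:
    """Fraction of posed atoms falling inside the sub-map mask (or grid)."""
    exp_map, submask = _experimental(map_or_submap)
    vox = np.rint(exp_map.world_to_voxel(pose.apply(model.xyz))).astype(int)
    inside = np.all((vox >= 0) & (vox < exp_map.grid.shape), axis=1)
    if submask is None:
        return float(inside.mean())
    hit = np.zeros(model.n_atoms, dtype=bool)
    hit[inside] = submask[tuple(vox[inside].T)]
    return float(hit.mean())


# ---------------------------------------------------------------------------
# Translation search
# ---------------------------------------------------------------------------

def translation_search(experimental: np.ndarray, template: np.ndarray,
                       method: str = "fft") -> np.ndarray:
    """Circular cross-correlation of a template against a map.

    ``out[dx, dy, dz] = sum_x experimental[x] * template[x - d]`` with
    periodic wrapping; the FFT route and the direct real-space scan are
    numerically identical (used as each other's oracle). Grids must share
    one shape.
    """
    if experimental.shape != template.shape:
        raise ValueError("experimental and template grids must share a shape")
    if method == "fft":
        fe = np.fft.rfftn(experimental.astype(np.float64))
        ft = np.fft.rfftn(template.astype(np.float64))
        return np.fft.irfftn(fe * np.conj(ft), s=experimental.shape, axes=(0, 1, 2))
    if method == "direct":
        e = experimental.astype(np.float64)
        t = template.astype(np.float64)
        out = np.empty(e.shape)
        for dx in range(e.shape[0]):
            for dy in range(e.shape[1]):
                for dz in range(e.shape[2]):
                    out[dx, dy, dz] = float(
                        np.sum(e * np.roll(t, (dx, dy, dz), axis=(0, 1, 2))))
        return out
    raise ValueError(f"unknown method {method!r}")


def best_shift(corr: np.ndarray) -> tuple[int, int, int]:
    """Deterministic argmax of a correlation volume (C-order first maximum),
    returned as signed voxel shifts (wrapped to the centred range)."""
    flat = int(np.argmax(corr))
    idx = np.unravel_index(flat, corr.shape)
    return tuple(int(i if i <= n // 2 else i - n)
                 for i, n in zip(idx, corr.shape))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Exhaustive docking
# ---------------------------------------------------------------------------

def _template_on_grid(model: AtomicModel, rotation: np.ndarray,
                      exp_map: DensityMap, resolution: float,
                      lowpass_template: bool = False,
                      ) -> tuple[DensityMap, np.ndarray]:
    """Rotated model rendered with its centroid on the grid centre voxel.

    Returns the template map and the pose translation that realises the
    zero-shift placement.
    """
    c = model.centroid()
    center_idx = (np.array(exp_map.grid.shape) // 2).astype(float)
    center_world = exp_map.voxel_to_world(center_idx)
    t0 = center_world - rotation @ c
    posed = model.transformed(rotation, t0)
    tmpl = simulate_map(posed, resolution, like=exp_map)
    if lowpass_template:
        tmpl = lowpass(tmpl, resolution)
    return tmpl, t0


def _local_rotation_offsets(angular_step: float) -> list[np.ndarray]:
    """Rotation-vector perturbations (deg) filling in below the grid spacing."""
    dirs = []
    for a in range(3):
        for s in (1.0, -1.0):
            v = np.zeros(3)
            v[a] = s
            dirs.append(v)
    mags = [angular_step / 3.0, 2.0 * angular_step / 3.0]
    return [m * d for m in mags for d in dirs]


def _pose_rmsd(p1: Pose, p2: Pose, ref_points: np.ndarray) -> float:
    """Symmetric chamfer RMS between the two placed point clouds.

    Nearest-neighbour matching (rather than index-wise RMSD) makes poses
    related by an internal symmetry of the model compare as equal, so
    symmetry-equivalent placements deduplicate to one.
    """
    a = p1.apply(ref_points)
    b = p2.apply(ref_points)
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(0.5 * (d2.min(axis=1).mean() + d2.min(axis=0).mean())))


def exhaustive_dock(candidate: Candidate | AtomicModel, submap: SubMap,
                    params: DockParams = DockParams()) -> list[FitResult]:
    """Dock one candidate into one sub-map over all sampled rotations.

    Per rotation, the best translation comes from the FFT correlation of
    the simulated template with the masked sub-map; each rotation's best
    pose is re-scored with :func:`cc_score`, poses closer than the
    deduplication RMSD collapse to the better-scoring one, and the top N
    survivors are ranked by CC (ties: smaller translation norm, then lower
    rotation-grid index).
    """
    if isinstance(candidate, Candidate):
        model, cand_id, source = candidate.model, candidate.candidate_id, candidate.source_id
    else:
        model, cand_id, source = candidate, "model", "model"
    if model.is_empty:
        raise ValueError("cannot dock an empty candidate")
    exp_map, _ = _experimental(submap)
    resolution = params.scoring_resolution or exp_map.resolution
    if resolution is None:
        raise ValueError("no scoring resolution available")
    extent = model.xyz.max(axis=0) - model.xyz.min(axis=0)
    box = np.array(exp_map.grid.shape) * exp_map.voxel
    if np.any(extent > box):
        warnings.warn(f"candidate {cand_id} exceeds the sub-map bounding box; "
                      "docking proceeds on a zero-padded grid")
    # pad so the largest template fits without circular-wrap artefacts
    needed = np.ceil((extent + 4.0 * 0.225 * resolution * 2 + 4.0)
                     / exp_map.voxel).astype(int) + 1
    target = np.maximum(np.array(exp_map.grid.shape), needed)
    if np.any(target > exp_map.grid.shape):
        pad = [(0, int(t - s)) for t, s in zip(target, exp_map.grid.shape)]
        padded_grid = np.pad(exp_map.grid, pad)
        exp_map = DensityMap(padded_grid, exp_map.voxel, exp_map.origin,
                             exp_map.resolution)
        submap = SubMap(exp_map, np.pad(submap.mask, pad), submap.label)
    exp_grid = exp_map.grid.astype(np.float64)
    fe = np.fft.rfftn(exp_grid)

    def fft_best_pose(R: np.ndarray, ridx: int) -> tuple[float, int, Pose]:
        tmpl, t0 = _template_on_grid(model, R, exp_map, resolution,
                                     params.lowpass_template)
        ft = np.fft.rfftn(tmpl.grid.astype(np.float64))
        corr = np.fft.irfftn(fe * np.conj(ft), s=exp_grid.shape, axes=(0, 1, 2))
        shift = best_shift(corr)
        peak = float(corr[tuple(np.array(shift) % exp_grid.shape)])
        norm = float(np.linalg.norm(tmpl.grid))
        raw = peak / norm if norm > 0 else NO_OVERLAP_CC
        t = t0 + np.array(shift) * exp_map.voxel
        return raw, ridx, Pose(R, t)

    # pass 1: coarse grid, best translation per rotation by raw correlation
    coarse = [fft_best_pose(R, i)
              for i, R in enumerate(rotation_grid(params.angular_step))]
    coarse.sort(key=lambda h: (-h[0], h[1]))
    hits = list(coarse)
    # pass 2: local rotation fill-in around the best coarse orientations
    if params.local_search_top > 0:
        offsets = _local_rotation_offsets(params.angular_step)
        extra_idx = len(coarse)
        for raw, ridx, pose0 in coarse[:params.local_search_top]:
            for off in offsets:
                dR = Rotation.from_rotvec(off, degrees=True).as_matrix()
                hits.append(fft_best_pose(dR @ pose0.rotation, extra_idx))
                extra_idx += 1
        hits.sort(key=lambda h: (-h[0], h[1]))
    # pass 3: true CC for the most promising poses only
    n_rescore = max(3 * params.top_n, 32)
    scored = [(cc_score(submap, model, pose, params),
               float(np.linalg.norm(pose.translation)), ridx, pose)
              for raw, ridx, pose in hits[:n_rescore]]
    scored.sort(key=lambda h: (-h[0], h[1], h[2]))
    # deduplicate: keep the best-scoring representative of each pose cluster
    n_ref = min(model.n_atoms, 50)
    ref_points = model.xyz[np.linspace(0, model.n_atoms - 1, n_ref).astype(int)]
    survivors: list[tuple[float, float, int, Pose]] = []
    for h in scored:
        if any(_pose_rmsd(h[3], s[3], ref_points) < params.dedup_rmsd
               for s in survivors):
            continue
        survivors.append(h)
        if len(survivors) >= params.top_n:
            break
    results = []
    for rank, (cc, _, _, pose) in enumerate(survivors, start=1):
        if params.refine:
            pose, cc = refine_pose(submap, model, pose, params)
        results.append(FitResult(cand_id, submap.label, pose, cc, rank, source))
    if params.refine:  # refinement can reorder the top N
        results.sort(key=lambda r: -r.cc)
        for rank, r in enumerate(results, start=1):
            r.rank = rank
    return results


def refine_pose(map_or_submap: DensityMap | SubMap, model: AtomicModel,
                pose: Pose, params: DockParams = DockParams(),
                max_iter: int = 150, simplex_rot: float | None = None,
                simplex_trans: float = 1.5) -> tuple[Pose, float]:
    """Local derivative-free polish of a pose (Nelder-Mead over 6 DoF).

    The parameterisation is a rotation-vector increment (degrees) about the
    model centroid plus a translation increment (Å), so the search stays
    well-scaled near the start pose. The initial simplex spans
    ``simplex_rot`` degrees (default: a third of the search grid's angular
    step, at least 5°) so refinement can cross the gap between coarse grid
    points and the true optimum.
    """
    if simplex_rot is None:
        simplex_rot = max(5.0, params.angular_step / 3.0)
    c = model.centroid()

    def build(x: np.ndarray) -> Pose:
        # extra rotation dR about the *placed* centroid, then a shift
        dR = Rotation.from_rotvec(x[:3], degrees=True).as_matrix()
        placed_c = pose.apply(c)
        R = dR @ pose.rotation
        t = placed_c - R @ c + x[3:]
        return Pose(R, t)

    def objective(x: np.ndarray) -> float:
        return -cc_score(map_or_submap, model, build(x), params)

    scales = [simplex_rot] * 3 + [simplex_trans] * 3
    res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 0.05, "fatol": 1e-5,
                            "initial_simplex": np.vstack(
                                [np.zeros(6), np.eye(6) * scales])})
    best = build(res.x)
    return best, -float(res.fun)


# ---------------------------------------------------------------------------
# Per-residue validation
# ---------------------------------------------------------------------------

def per_residue_cc(model: AtomicModel, dmap: DensityMap,
                   params: DockParams = DockParams(),
                   mask_radius: float = 2.5) -> pd.DataFrame:
    """Map-to-model CC per residue for a model already placed in the map frame.

    For each residue the CC runs over voxels within ``mask_radius`` Å of its
    atoms. The report flags residues below the 0.7 (good) and 0.5 (poor)
    bands conventionally used when judging local map-model agreement.
    Residues without atoms inside the grid are omitted with a warning.
    """
    resolution = params.scoring_resolution or dmap.resolution
    if resolution is None:
        raise ValueError("no scoring resolution available")
    sim = simulate_map(model, resolution, like=dmap)
    shape = dmap.grid.shape
    rows = []
    for ch, rn, idx in model.residues():
        vox = dmap.world_to_voxel(model.xyz[idx])
        lo = np.maximum(np.floor(vox.min(axis=0) - mask_radius / dmap.voxel
                                 ).astype(int), 0)
        hi = np.minimum(np.ceil(vox.max(axis=0) + mask_radius / dmap.voxel
                                ).astype(int) + 1, shape)
        if np.any(lo >= hi):
            warnings.warn(f"residue {ch}/{rn} lies outside the map; omitted")
            continue
        sub_idx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
        diff = (sub_idx[:, None, :] - vox[None, :, :]) * dmap.voxel
        within = (np.sum(diff * diff, axis=2).min(axis=1)
                  <= mask_radius * mask_radius)
        if not within.any():
            warnings.warn(f"residue {ch}/{rn} has no voxels within "
                          f"{mask_radius} Å; omitted")
            continue
        sel = tuple(sub_idx[within].T)
        cc = _pearson(dmap.grid[sel], sim.grid[sel])
        rows.append({"chain": ch, "resnum": rn, "cc": cc,
                     "below_0.7": cc < 0.7, "below_0.5": cc < 0.5})
    return pd.DataFrame(rows)
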