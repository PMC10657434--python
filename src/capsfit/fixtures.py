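"""Seeded synthetic scenes: toy proteins, density maps, ground truth.

Real capsid-end maps are large experimental depositions; the screening
machinery, however, only needs scenes with the right *structure*: several
distinct rigid bodies rendered into a band-limited, noisy density map with
a recorded ground truth. This module builds such scenes deterministically
from a seed.

Toy proteins use idealised backbone geometry (consecutive Cα–Cα spacing
3.8 Å; N, C, O, Cβ placed from the Cα trace) rather than real folds, so no
structural database is required. Default scene conditions mirror the
screening problem: 3 true proteins plus 10 decoy models, maps low-passed
to 6 Å, white Gaussian real-space noise at SNR 10.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .helix import apply_cn
from .rigid import Pose
from .structio import AtomicModel, DensityMap
from .voldens import lowpass, simulate_map

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_toy_protein",
    "make_scene",
    "make_assignment_scene",
    "make_split_protein_scene",
    "make_capsid_end_scene",
    "random_pose",
]

CA_SPACING = 3.8  # Å, consecutive Cα distance enforced by construction

DEFAULT_RESOLUTION = 6.0  # Å
DEFAULT_VOXEL = 2.5  # Å
DEFAULT_SNR = 10.0
DEFAULT_N_DECOYS = 10


# ---------------------------------------------------------------------------
# Toy proteins
# ---------------------------------------------------------------------------

def _helix_points(n: int, phase: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix Cα trace along +z (spacing ~3.8 Å)."""
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    i = np.arange(n)
    return np.column_stack([radius * np.cos(turn * i + phase),
                            radius * np.sin(turn * i + phase),
                            rise * i])


def _connector(p_from: np.ndarray, p_to: np.ndarray, n_loop: int) -> np.ndarray:
    """``n_loop`` points evenly spaced strictly between two anchors."""
    ts = np.linspace(0.0, 1.0, n_loop + 2)[1:-1]
    return p_from + ts[:, None] * (p_to - p_from)


def _bundle_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Up-down helix bundle; loops are straight runs of exactly 3.8 Å steps.

    The seed varies helix lengths, phases and the packing layout, so
    different seeds give geometrically distinct bundles.
    """
    n_loop = 3
    pts: list[np.ndarray] = []
    remaining = length
    col = 0
    prev_end: np.ndarray | None = None
    lateral_dirs = [np.array([1.0, 0.0, 0.0]), np.array([0.35, 0.94, 0.0]),
                    np.array([-1.0, 0.0, 0.0]), np.array([0.35, -0.94, 0.0])]
    pack = float(rng.uniform(9.0, 12.0))  # helix-helix packing distance
    col_pos = np.zeros(3)
    while remaining > 0:
        if prev_end is not None and remaining <= n_loop + 3:
            # tail too short for another helix: continue in a straight run
            direction = lateral_dirs[int(rng.integers(0, 4))] + \
                np.array([0.0, 0.0, 0.3])
            direction /= np.linalg.norm(direction)
            tail = prev_end + CA_SPACING * np.arange(1, remaining + 1)[:, None] \
                * direction
            pts.append(tail)
            break
        seg = int(rng.integers(10, 17))
        nl = n_loop if prev_end is not None else 0
        n_helix = max(3, min(seg, remaining - nl))
        helix = _helix_points(n_helix, phase=float(rng.uniform(0, 2 * np.pi)))
        if col % 2 == 1:
            helix = helix @ np.diag([1.0, -1.0, -1.0])  # 180° about x: run down
        if prev_end is None:
            helix = helix - helix[0]
        else:
            gap = CA_SPACING * (nl + 1)
            lateral = pack * lateral_dirs[int(rng.integers(0, 4))] \
                if col > 1 else pack * lateral_dirs[0]
            col_pos = col_pos + lateral
            dz = np.sqrt(max(gap ** 2 - lateral @ lateral, 1.0))
            start = prev_end + lateral + np.array([0.0, 0.0,
                                                   dz if col % 2 else -dz])
            pts.append(_connector(prev_end, start, nl))
            helix = helix - helix[0] + start
        pts.append(helix)
        prev_end = helix[-1]
        remaining -= n_helix + nl
        col += 1
    return np.vstack(pts)[:length]


def _sandwich_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Two stacked sheets of antiparallel zigzag strands with short turns.

    Strand lengths, sheet spacing and an inter-sheet twist are all drawn
    from the seed, so two sandwiches of the same length are still distinct
    folds."""
    strand_sep = float(rng.uniform(4.4, 5.2))
    sheet_sep = float(rng.uniform(8.5, 10.5))
    axial, zig = 3.3, 0.95  # step = sqrt(axial^2 + (2 zig)^2) ~ 3.8
    s_len = int(rng.integers(6, 10))
    x_jitter = float(rng.uniform(-0.5, 0.5))
    sheet_twist = np.deg2rad(float(rng.uniform(-35.0, 35.0)))
    per_strand = {idx: int(rng.integers(5, 11)) for idx in range(16)}

    def strand_points(idx: int, n: int) -> np.ndarray:
        i = np.arange(n)
        sheet = (idx // 2) % 2  # two strands per sheet, then hop sheets
        row = (idx % 2) + 2 * (idx // 4)
        z = axial * i
        if idx % 2 == 1:
            z = axial * (n - 1) - z  # antiparallel partner, top down
        pts = np.column_stack([
            sheet * (sheet_sep + x_jitter)
            + zig * np.where(i % 2 == 0, 1.0, -1.0),
            np.full(n, row * strand_sep),
            z])
        if sheet == 1:  # second sheet rotated about its own x-axis
            c, s = np.cos(sheet_twist), np.sin(sheet_twist)
            pivot = np.array([0.0, axial * s_len / 2])
            pts[:, 1:] = (pts[:, 1:] - pivot) @ np.array([[c, -s], [s, c]]).T \
                + pivot
        return pts

    pts: list[np.ndarray] = [strand_points(0, min(per_strand[0], length))]
    remaining = length - len(pts[0])
    idx = 1
    while remaining > 0:
        prev_end = pts[-1][-1]
        s_len_i = per_strand[idx % 16]
        start = strand_points(idx, s_len_i)[0]
        gap = float(np.linalg.norm(start - prev_end))
        if gap < 2 * CA_SPACING - 0.4:
            nl, lift = 1, True  # short hairpin: one lifted apex residue
        else:
            nl, lift = max(1, int(round(gap / CA_SPACING)) - 1), False
        if remaining - nl < 1:
            # tail: straight 3.8 Å steps away from the sandwich
            direction = np.array([0.3, 0.3, 1.0]) / np.linalg.norm([0.3, 0.3, 1.0])
            pts.append(prev_end + CA_SPACING
                       * np.arange(1, remaining + 1)[:, None] * direction)
            break
        if lift:
            chord = start - prev_end
            perp = np.cross(chord, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(chord, np.array([1.0, 0.0, 0.0]))
            perp /= np.linalg.norm(perp)
            h = np.sqrt(max(CA_SPACING ** 2 - (gap / 2) ** 2, 0.25))
            pts.append((0.5 * (prev_end + start) + h * perp)[None, :])
        else:
            pts.append(_connector(prev_end, start, nl))
        remaining -= nl
        n = min(s_len_i, remaining)
        pts.append(strand_points(idx, n))
        remaining -= n
        idx += 1
    return np.vstack(pts)[:length]


def _coil_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding random walk with fixed 3.8 Å steps.

    A weak pull toward the running centroid keeps the coil globular rather
    than extended."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(length - 1):
        centroid = np.mean(pts, axis=0)
        for _attempt in range(60):
            inward = centroid - pts[-1]
            norm = np.linalg.norm(inward)
            inward = inward / norm if norm > 1e-9 else np.zeros(3)
            new_dir = direction + rng.normal(0, 1.3, size=3) + 0.5 * inward
            new_dir /= np.linalg.norm(new_dir)
            cand = pts[-1] + CA_SPACING * new_dir
            if len(pts) < 3:
                break
            dmin = np.min(np.linalg.norm(np.array(pts[:-1]) - cand, axis=1))
            if dmin > 3.9:
                break
        direction = new_dir
        pts.append(cand)
    return np.array(pts)


def _backbone_from_ca(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Approximate N, C, O, Cβ positions from a Cα trace.

    Geometric placement only — good enough for density rendering, not for
    stereochemistry. Returns (positions, atom-name index array) with atoms
    ordered N, CA, C, O, CB per residue.
    """
    n_res = len(ca)
    tang = np.zeros_like(ca)
    tang[1:-1] = ca[2:] - ca[:-2]
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    side = np.cross(tang, ref)
    bad = np.linalg.norm(side, axis=1) < 1e-6
    side[bad] = np.cross(tang[bad], np.array([0.0, 1.0, 0.0]))
    side /= np.linalg.norm(side, axis=1, keepdims=True)
    up = np.cross(tang, side)
    atoms = np.empty((n_res, 5, 3))
    atoms[:, 0] = ca - 1.46 * tang * 0.5 + 0.6 * side  # N
    atoms[:, 1] = ca  # CA
    atoms[:, 2] = ca + 1.52 * tang * 0.5 + 0.6 * side  # C
    atoms[:, 3] = atoms[:, 2] + 1.23 * up  # O
    atoms[:, 4] = ca - 1.53 * up  # CB
    return atoms.reshape(-1, 3), np.tile(np.arange(5), n_res)


_ATOM_NAMES = np.array(["N", "CA", "C", "O", "CB"], dtype=object)
_ELEMENTS = np.array(["N", "C", "C", "O", "C"], dtype=object)


def make_toy_protein(kind: str, length: int, seed: int = 0,
                     confidence: float | tuple[float, float] = 90.0,
                     chain: str = "A") -> AtomicModel:
    """Build an idealised toy protein (backbone + Cβ, ALA residues).

    ``kind`` is one of ``helix-bundle``, ``beta-sandwich``, ``random-coil``.
    ``confidence`` is either a uniform per-residue value or a
    ``(start, end)`` pair producing a linear N-to-C ramp (pLDDT-like,
    0–100). Deterministic for a fixed seed.
    """
    if length < 10:
        raise ValueError("toy proteins need length >= 10")
    rng = np.random.default_rng(seed)
    if kind == "helix-bundle":
        ca = _bundle_trace(length, rng)
    elif kind == "beta-sandwich":
        ca = _sandwich_trace(length, rng)
    elif kind == "random-coil":
        ca = _coil_trace(length, rng)
    else:
        raise ValueError(f"unknown toy protein kind {kind!r}")
    ca = ca - ca.mean(axis=0)
    xyz, name_idx = _backbone_from_ca(ca)
    resnum = np.repeat(np.arange(1, length + 1), 5)
    if isinstance(confidence, tuple):
        per_res = np.linspace(confidence[0], confidence[1], length)
    else:
        per_res = np.full(length, float(confidence))
    return AtomicModel(
        chain=np.full(5 * length, chain, dtype=object),
        resnum=resnum,
        resname=np.full(5 * length, "ALA", dtype=object),
        atname=_ATOM_NAMES[name_idx],
        element=_ELEMENTS[name_idx],
        xyz=xyz,
        confidence=per_res[resnum - 1],
        occupancy=np.ones(5 * length),
    )


def random_pose(rng: np.random.Generator,
                translation_box: float = 0.0) -> Pose:
    """Haar-uniform random rotation plus a uniform translation in a box."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    t = rng.uniform(-translation_box / 2, translation_box / 2, size=3) \
        if translation_box else np.zeros(3)
    return Pose(R, t)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SceneSpec:
    """Everything needed to rebuild a scene deterministically."""

    models: dict[str, AtomicModel]  # true models by id
    placements: list[tuple[str, Pose]]  # (model id, pose in world frame)
    decoy_pool_size: int = DEFAULT_N_DECOYS
    resolution: float = DEFAULT_RESOLUTION
    voxel: float = DEFAULT_VOXEL
    snr: float = DEFAULT_SNR
    seed: int = 0
    padding: float = 10.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        for mid, _ in self.placements:
            if mid not in self.models:
                raise ValueError(f"placement references unknown model {mid!r}")


@dataclasses.dataclass
class GroundTruth:
    """Poses, identities and noise level sufficient to score any result."""

    spec: SceneSpec
    poses: dict[str, Pose]
    decoys: dict[str, AtomicModel]
    noise_sigma: float
    clean_map: DensityMap | None = None

    @property
    def true_ids(self) -> list[str]:
        return list(self.poses)

    def all_sources(self) -> dict[str, AtomicModel]:
        """True models plus decoys, in their original (unplaced) frames."""
        return {**self.spec.models, **self.decoys}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.spec.seed,
            "resolution": self.spec.resolution,
            "voxel": self.spec.voxel,
            "snr": self.spec.snr,
            "noise_sigma": self.noise_sigma,
            "true_ids": self.true_ids,
            "decoy_ids": list(self.decoys),
            "poses": {mid: [round(v, 9) for v in pose.as_flat()]
                      for mid, pose in self.poses.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


_CLASH_DISTANCE = 3.0  # Å between atoms of different placed models


def _decoy_models(rng: np.random.Generator, n: int) -> dict[str, AtomicModel]:
    kinds = ["helix-bundle", "beta-sandwich", "random-coil"]
    out = {}
    for i in range(n):
        kind = kinds[i % 3]
        length = int(rng.integers(30, 46))
        seed = int(rng.integers(0, 2 ** 31 - 1))
        out[f"decoy{i:02d}"] = make_toy_protein(kind, length, seed)
    return out


def make_scene(spec: SceneSpec) -> tuple[DensityMap, GroundTruth]:
    """Render placed models into a noisy band-limited map with ground truth.

    All placed models are simulated together, low-passed to the stated
    resolution, and white Gaussian noise is added so that (in-mask signal
    variance) / (noise variance) equals the requested SNR. Raises on
    clashing placements.
    """
    rng = np.random.default_rng(spec.seed)
    placed = [spec.models[mid].transformed(p.rotation, p.translation)
              for mid, p in spec.placements]
    if not placed:
        raise ValueError("scene has no placements")
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            if cdist(placed[i].xyz, placed[j].xyz).min() < _CLASH_DISTANCE:
                raise ValueError(
                    f"placements {spec.placements[i][0]!r} and "
                    f"{spec.placements[j][0]!r} clash (< {_CLASH_DISTANCE} Å)")
    merged = AtomicModel.concatenate(placed)
    clean = simulate_map(merged, spec.resolution, voxel=spec.voxel,
                         padding=spec.padding)
    clean = lowpass(clean, spec.resolution)
    signal_mask = clean.grid > 0.1 * clean.grid.max()
    signal_var = float(clean.grid[signal_mask].astype(np.float64).var())
    sigma = float(np.sqrt(signal_var / spec.snr))
    noisy = clean.copy()
    noisy.grid = (clean.grid
                  + rng.normal(0.0, sigma, size=clean.grid.shape)
                  ).astype(np.float32)
    truth = GroundTruth(
        spec=spec,
        poses=dict(spec.placements),
        decoys=_decoy_models(rng, spec.decoy_pool_size),
        noise_sigma=sigma,
        clean_map=clean,
    )
    return noisy, truth


def make_assignment_scene(seed: int, n_true: int = 3,
                          n_decoys: int = DEFAULT_N_DECOYS,
                          resolution: float = DEFAULT_RESOLUTION,
                          voxel: float = DEFAULT_VOXEL,
                          snr: float = DEFAULT_SNR,
                          ) -> tuple[DensityMap, GroundTruth]:
    """Standard screening scene: n distinct true proteins in one 'asymmetric
    unit' wedge plus a pool of decoys, at the default map conditions."""
    rng = np.random.default_rng(seed)
    kinds = ["helix-bundle", "beta-sandwich", "random-coil"]
    lengths = [40, 40, 32, 38, 36]
    models = {}
    placements = []
    anchors = np.array([[0.0, 0.0, 0.0], [48.0, 0.0, 0.0], [24.0, 42.0, 0.0],
                        [72.0, 42.0, 0.0], [-24.0, 42.0, 0.0]])
    for i in range(n_true):
        mid = f"true{i}"
        models[mid] = make_toy_protein(kinds[i % 3], lengths[i % len(lengths)],
                                       seed=int(rng.integers(0, 2 ** 31 - 1)))
        pose = random_pose(rng)
        placements.append((mid, Pose(pose.rotation, anchors[i])))
    spec = SceneSpec(models=models, placements=placements,
                     decoy_pool_size=n_decoys, resolution=resolution,
                     voxel=voxel, snr=snr, seed=seed)
    return make_scene(spec)


def make_split_protein_scene(seed: int = 0,
                             resolution: float = DEFAULT_RESOLUTION,
                             voxel: float = DEFAULT_VOXEL,
                             snr: float = DEFAULT_SNR,
                             ) -> tuple[DensityMap, GroundTruth]:
    """One elongated two-domain protein whose thin linker falls below the
    segmentation threshold, so the blob splits into two sub-maps — the
    fixture that the half-model round is meant to rescue."""
    rng = np.random.default_rng(seed)
    dom_a = make_toy_protein("helix-bundle", 30,
                             seed=int(rng.integers(0, 2 ** 31 - 1)))
    dom_b = make_toy_protein("beta-sandwich", 30,
                             seed=int(rng.integers(0, 2 ** 31 - 1)))
    # join the domains with a straight 8-residue linker along +x
    a_xyz = dom_a.xyz
    shift = np.array([44.0, 0.0, 0.0])
    b = dom_b.copy()
    b.xyz = dom_b.xyz + shift
    b.resnum = dom_b.resnum + 38  # 30 domain + 8 linker residues
    a_end = a_xyz[dom_a.resnum == 30].mean(axis=0)
    b_start = b.xyz[b.resnum == 39].mean(axis=0)
    link_ca = _connector(a_end, b_start, 8)
    # Cα-only linker: thin density that falls below segmentation thresholds
    linker = AtomicModel(
        chain=np.full(len(link_ca), "A", dtype=object),
        resnum=np.arange(31, 39),
        resname=np.full(len(link_ca), "ALA", dtype=object),
        atname=np.full(len(link_ca), "CA", dtype=object),
        element=np.full(len(link_ca), "C", dtype=object),
        xyz=link_ca, confidence=np.full(len(link_ca), 90.0),
        occupancy=np.ones(len(link_ca)))
    protein = AtomicModel.concatenate([dom_a, linker, b])
    spec = SceneSpec(models={"split": protein},
                     placements=[("split", Pose.identity())],
                     decoy_pool_size=4, resolution=resolution, voxel=voxel,
                     snr=snr, seed=seed)
    return make_scene(spec)


def make_capsid_end_scene(n_proteins: int = 3, symmetry_order: int = 14,
                          seed: int = 0, inner_order: int | None = None,
                          radius: float = 60.0,
                          resolution: float = DEFAULT_RESOLUTION,
                          voxel: float = 2.5, snr: float = DEFAULT_SNR,
                          ) -> tuple[DensityMap, GroundTruth]:
    """A C-symmetric end-cap: one asymmetric unit of distinct toy proteins
    replicated about +z, optionally with an inner ring of lower order
    (emulating an outer shell with a central plug of half the order).

    The asymmetric-unit proteins sit at ``radius`` from the axis; when
    ``inner_order`` is given an extra protein ring is placed at one third
    of the radius with that order.
    """
    if symmetry_order < 2:
        raise ValueError("symmetry order must be >= 2")
    rng = np.random.default_rng(seed)
    kinds = ["helix-bundle", "beta-sandwich", "random-coil"]
    models: dict[str, AtomicModel] = {}
    asym_parts = []
    for i in range(n_proteins):
        mid = f"asym{i}"
        toy = make_toy_protein(kinds[i % 3], 34,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
        models[mid] = toy
        pose = random_pose(rng)
        # spread the unit's proteins azimuthally within one wedge
        ang = (i - (n_proteins - 1) / 2) * (300.0 / symmetry_order)
        anchor = np.array([radius * np.cos(np.deg2rad(ang)),
                           radius * np.sin(np.deg2rad(ang)), 0.0])
        asym_parts.append(toy.transformed(pose.rotation, anchor))
    unit = AtomicModel.concatenate(asym_parts)
    ring = apply_cn(unit, symmetry_order)
    parts = [ring]
    if inner_order is not None:
        inner_toy = make_toy_protein("helix-bundle", 30,
                                     seed=int(rng.integers(0, 2 ** 31 - 1)))
        inner_unit = inner_toy.translated(
            np.array([radius / 3.0, 0.0, -10.0]))
        parts.append(apply_cn(inner_unit, inner_order))
        models["inner"] = inner_toy
    scene_model = AtomicModel.concatenate(parts)
    clean = simulate_map(scene_model, resolution, voxel=voxel, padding=10.0)
    clean = lowpass(clean, resolution)
    signal_mask = clean.grid > 0.1 * clean.grid.max()
    sigma = float(np.sqrt(clean.grid[signal_mask].astype(np.float64).var()
                          / snr))
    noisy = clean.copy()
    noisy.grid = (clean.grid + rng.normal(0.0, sigma, size=clean.grid.shape)
                  ).astype(np.float32)
    spec = SceneSpec(models=models, placements=[], decoy_pool_size=0,
                     resolution=resolution, voxel=voxel, snr=snr, seed=seed)
    truth = GroundTruth(spec=spec, poses={}, decoys={}, noise_sigma=sigma,
                        clean_map=clean)
    return noisy, truth
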