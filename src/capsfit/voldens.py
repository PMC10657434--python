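"""Density simulation, filtering, segmentation and subtraction.

The docking stages need four map-side primitives:

* :func:`simulate_map` renders an atomic model as a sum of isotropic
  Gaussians (sigma = 0.225 x resolution, amplitude proportional to atomic
  number) — the reference density that map-to-model correlation is scored
  against;
* :func:`lowpass` applies a cosine-edge Fourier filter, used to bring
  simulated scenes to the nominal resolution of an experimental map;
* :func:`segment_map` splits a map into candidate protein "blobs"
  (sub-maps) by thresholded connected components, optionally refined by a
  watershed split at density saddle points — the algorithmic counterpart of
  segmenting an asymmetric unit into resolvable densities by eye;
* :func:`subtract_fitted` removes the density explained by accepted model
  placements so later, finer screening rounds only see what is left.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .rigid import Pose
from .structio import AtomicModel, DensityMap, write_map

__all__ = [
    "SubMap",
    "SIGMA_PER_RESOLUTION",
    "simulate_map",
    "lowpass",
    "segment_map",
    "subtract_fitted",
]

#: Gaussian spread per Å of nominal resolution (common generator convention).
SIGMA_PER_RESOLUTION = 0.225

_CUTOFF_SIGMAS = 4.0  # atoms contribute within 4 sigma of their centre
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class SubMap:
    """A labelled sub-volume of a parent map, represented as a boolean mask."""

    parent: DensityMap
    mask: np.ndarray
    label: str
    level: float = 0.0  # density level that defined the segmentation

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.parent.grid.shape:
            raise ValueError("mask shape differs from parent grid shape")
        if not self.mask.any():
            raise ValueError(f"sub-map {self.label!r} has an empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Mask volume in Å^3."""
        return self.n_voxels * self.parent.voxel_volume

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return self.parent.voxel_to_world(idx.mean(axis=0))

    def masked_map(self) -> DensityMap:
        """Parent density with everything outside the mask zeroed."""
        out = self.parent.copy()
        out.grid = np.where(self.mask, out.grid, 0.0).astype(np.float32)
        return out

    def density_sum(self) -> float:
        return float(self.parent.grid[self.mask].sum())

    def cropped(self, margin: float = 8.0) -> "SubMap":
        """Sub-map restricted to its mask bounding box plus ``margin`` Å.

        The cropped parent grid is zeroed outside the mask and keeps world
        coordinates consistent (origin shifts with the crop), so poses found
        in the cropped frame are valid in the full-map frame.
        """
        idx = np.argwhere(self.mask)
        mv = np.ceil(margin / self.parent.voxel).astype(int)
        lo = np.maximum(idx.min(axis=0) - mv, 0)
        hi = np.minimum(idx.max(axis=0) + mv + 1,
                        np.array(self.parent.grid.shape))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grid = np.where(self.mask, self.parent.grid, 0.0)[sl]
        parent = DensityMap(grid, self.parent.voxel,
                            self.parent.origin + lo * self.parent.voxel,
                            self.parent.resolution)
        return SubMap(parent, self.mask[sl], self.label, self.level)

    def with_parent_grid(self, grid: np.ndarray) -> "SubMap":
        """Same geometry and mask over replacement density values."""
        parent = DensityMap(grid, self.parent.voxel, self.parent.origin,
                            self.parent.resolution)
        return SubMap(parent, self.mask.copy(), self.label, self.level)

    def write(self, map_path: str | Path, mask_path: str | Path) -> None:
        write_map(self.masked_map(), map_path)
        write_map(DensityMap(self.mask.astype(np.float32), self.parent.voxel,
                             self.parent.origin), mask_path)


def segmentation_report(submaps: Sequence[SubMap]) -> pd.DataFrame:
    rows = []
    for sm in submaps:
        cx, cy, cz = sm.centroid_world()
        rows.append({"label": sm.label, "voxels": sm.n_voxels,
                     "volume_A3": sm.volume,
                     "centroid_x": cx, "centroid_y": cy, "centroid_z": cz})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _check_sampling(resolution: float, voxel: float) -> None:
    if resolution < 2.0 * voxel - 1e-9:
        raise ValueError(
            f"resolution {resolution} Å under-samples a {voxel} Å grid "
            "(need resolution >= 2 x voxel)")


def simulate_map(model: AtomicModel, resolution: float, voxel: float = 1.0,
                 padding: float = 5.0, like: DensityMap | None = None,
                 ) -> DensityMap:
    """Render a model as Gaussian atoms on a regular grid.

    Each atom contributes ``Z * exp(-r^2 / (2 sigma^2))`` with
    ``sigma = 0.225 * resolution`` and Z its atomic number; contributions
    are truncated beyond 4 sigma. By default the grid is sized to enclose
    the model plus ``padding`` Å on every side; pass ``like`` to render
    onto the grid geometry (shape, voxel, origin) of an existing map, e.g.
    to compare against experimental density.
    """
    if model.is_empty:
        raise ValueError("cannot simulate density for an empty model")
    if like is not None:
        voxel_vec = like.voxel.copy()
        _check_sampling(resolution, float(voxel_vec.max()))
        origin = like.origin.copy()
        shape = like.grid.shape
    else:
        _check_sampling(resolution, voxel)
        voxel_vec = np.full(3, float(voxel))
        lo = model.xyz.min(axis=0) - padding
        hi = model.xyz.max(axis=0) + padding
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_vec[i])) + 1
                      for i in range(3))
        origin = lo
    sigma = SIGMA_PER_RESOLUTION * resolution
    cutoff = _CUTOFF_SIGMAS * sigma
    grid = np.zeros(shape, dtype=np.float64)
    weights = model.atomic_numbers()
    centers = (model.xyz - origin) / voxel_vec  # fractional voxel coords
    half = np.ceil(cutoff / voxel_vec).astype(int)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    # vectorised separable splat: every atom writes a (2h+1)^3 window
    base = np.floor(centers).astype(int)  # (n, 3)
    profs, idxs, valid = [], [], []
    for a in range(3):
        offs = np.arange(-half[a], half[a] + 1)
        idx = base[:, a, None] + offs[None, :]  # (n, w)
        ok = (idx >= 0) & (idx < shape[a])
        d = (idx - centers[:, a, None]) * voxel_vec[a]
        prof = np.exp(-d * d * inv2s2)
        prof[~ok] = 0.0
        idxs.append(np.clip(idx, 0, shape[a] - 1))
        profs.append(prof)
    vals = (profs[0][:, :, None, None] * profs[1][:, None, :, None]
            * profs[2][:, None, None, :]) * weights[:, None, None, None]
    lin = (idxs[0][:, :, None, None] * (shape[1] * shape[2])
           + idxs[1][:, None, :, None] * shape[2]
           + idxs[2][:, None, None, :])
    np.add.at(grid.ravel(), lin.ravel(), vals.ravel())
    out = DensityMap(grid, voxel_vec, origin, resolution)
    return out


def gaussian_integral(resolution: float) -> float:
    """Analytic integral (Å^3) of one unit-amplitude simulated atom."""
    sigma = SIGMA_PER_RESOLUTION * resolution
    return float((2.0 * np.pi) ** 1.5 * sigma ** 3)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def lowpass(dmap: DensityMap, resolution: float,
            edge_width_fraction: float = 0.2) -> DensityMap:
    """Cosine-edge low-pass filter to the given resolution.

    Fourier amplitudes are kept below ``fc - w/2``, rolled off with a raised
    cosine of full width ``w = edge_width_fraction * fc`` centred on the
    cutoff ``fc = 1/resolution``, and zeroed beyond ``fc + w/2``. The zero
    frequency is in the pass band, so the map mean is preserved.
    """
    _check_sampling(resolution, float(dmap.voxel.max()))
    fc = 1.0 / resolution
    w = edge_width_fraction * fc
    freqs = [np.fft.fftfreq(n, d=dmap.voxel[i]) for i, n in
             enumerate(dmap.grid.shape[:2])]
    freqs.append(np.fft.rfftfreq(dmap.grid.shape[2], d=dmap.voxel[2]))
    f = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                + freqs[2][None, None, :] ** 2)
    H = np.ones_like(f)
    lo, hi = fc - w / 2.0, fc + w / 2.0
    ramp = (f > lo) & (f < hi)
    H[ramp] = 0.5 * (1.0 + np.cos(np.pi * (f[ramp] - lo) / (hi - lo)))
    H[f >= hi] = 0.0
    spec = np.fft.rfftn(dmap.grid.astype(np.float64)) * H
    out = dmap.copy()
    out.grid = np.fft.irfftn(spec, s=dmap.grid.shape, axes=(0, 1, 2)).astype(np.float32)
    out.resolution = resolution
    return out


def cosine_edge_gain(f: float, resolution: float,
                     edge_width_fraction: float = 0.2) -> float:
    """Closed-form gain of the low-pass filter at spatial frequency ``f``."""
    fc = 1.0 / resolution
    w = edge_width_fraction * fc
    lo, hi = fc - w / 2.0, fc + w / 2.0
    if f <= lo:
        return 1.0
    if f >= hi:
        return 0.0
    return 0.5 * (1.0 + np.cos(np.pi * (f - lo) / (hi - lo)))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_map(dmap: DensityMap, threshold: float,
                min_volume: float = 0.0, method: str = "connected",
                ) -> list[SubMap]:
    """Split a map into sub-maps of contiguous density above a threshold.

    ``connected`` labels 26-connected components of ``grid > threshold``;
    ``watershed`` further splits components at density saddle points
    (basins of the inverted map seeded at local maxima). Components smaller
    than ``min_volume`` (Å^3) are discarded. Sub-maps are returned sorted by
    volume, largest first, labelled ``blob01``, ``blob02``, ...
    """
    if method not in ("connected", "watershed"):
        raise ValueError(f"unknown segmentation method {method!r}")
    above = dmap.grid > threshold
    if not above.any():
        warnings.warn(f"threshold {threshold} is above the map maximum "
                      f"({dmap.grid.max():.4g}); no sub-maps")
        return []
    if method == "connected":
        labels, n = ndimage.label(above, structure=_CONN26)
    else:
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        # seed one basin per local maximum separated by at least ~2 voxels
        peaks = peak_local_max(dmap.grid.astype(float), min_distance=2,
                               labels=above, exclude_border=False)
        markers = np.zeros(dmap.grid.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        labels = watershed(-dmap.grid.astype(float), markers=markers, mask=above)
        n = labels.max()
    min_vox = min_volume / dmap.voxel_volume
    comps = []
    for lab in range(1, n + 1):
        mask = labels == lab
        size = int(mask.sum())
        if size and size >= min_vox:
            comps.append((size, lab, mask))
    comps.sort(key=lambda t: (-t[0], t[1]))
    return [SubMap(dmap, mask, f"blob{i:02d}", level=threshold)
            for i, (_, _, mask) in enumerate(comps, start=1)]


# ---------------------------------------------------------------------------
# Subtraction
# ---------------------------------------------------------------------------

def subtract_fitted(dmap: DensityMap,
                    placements: Sequence[tuple[AtomicModel, Pose]],
                    mask_radius: float = 3.0, soft_edge: float = 3.0,
                    ) -> DensityMap:
    """Remove the density explained by placed models.

    Voxels within ``mask_radius`` Å of any posed atom are scaled to zero,
    with a cosine soft edge of width ``soft_edge`` Å beyond the radius;
    voxels farther away are untouched. Masking to zero (rather than
    subtracting a simulated map) is robust to amplitude mismatch at
    intermediate resolution.
    """
    if not placements:
        return dmap.copy()
    occupied = np.zeros(dmap.grid.shape, dtype=bool)
    any_atom = False
    for model, pose in placements:
        if model.is_empty:
            continue
        vox = np.rint(dmap.world_to_voxel(pose.apply(model.xyz))).astype(int)
        inside = np.all((vox >= 0) & (vox < dmap.grid.shape), axis=1)
        if inside.any():
            occupied[tuple(vox[inside].T)] = True
            any_atom = True
    if not any_atom:
        return dmap.copy()
    # distance (Å) from each voxel centre to the nearest atom-occupied voxel
    dist = ndimage.distance_transform_edt(~occupied, sampling=dmap.voxel)
    factor = np.ones_like(dist)
    factor[dist <= mask_radius] = 0.0
    if soft_edge > 0:
        ramp = (dist > mask_radius) & (dist < mask_radius + soft_edge)
        factor[ramp] = 0.5 * (1.0 - np.cos(
            np.pi * (dist[ramp] - mask_radius) / soft_edge))
    out = dmap.copy()
    out.grid = (out.grid * factor).astype(np.float32)
    return out
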