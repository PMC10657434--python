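"""Density simulation, low-pass filtering, segmentation, subtraction."""

import numpy as np
import pytest

from capsfit.fixtures import make_toy_protein
from capsfit.rigid import Pose
from capsfit.structio import DensityMap
from capsfit.voldens import (cosine_edge_gain, gaussian_integral, lowpass,
                             segment_map, simulate_map, subtract_fitted)

from conftest import build_model


def _carbon_at(xyz):
    return build_model([("A", 1, "ALA", "CA", "C", tuple(xyz), 90.0)])


class TestSimulate:
    def test_single_atom_peaks_at_atom_position(self):
        m = _carbon_at((3.0, 4.0, 5.0))
        dmap = simulate_map(m, resolution=4.0, voxel=1.0, padding=6.0)
        peak_idx = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
        peak_world = dmap.voxel_to_world(np.array(peak_idx))
        assert np.allclose(peak_world, [3.0, 4.0, 5.0], atol=1.0)

    def test_linearity_in_atomic_number(self):
        c = _carbon_at((0.0, 0.0, 0.0))
        s = c.copy()
        s.element = np.array(["Mg"], object)  # Z=12, exactly 2x carbon
        a = simulate_map(c, 4.0, voxel=1.0, padding=5.0)
        b = simulate_map(s, 4.0, voxel=1.0, padding=5.0)
        assert np.allclose(b.grid, 2.0 * a.grid, atol=1e-6)

    def test_integral_matches_analytic_gaussian(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        res = 5.0
        dmap = simulate_map(m, res, voxel=1.0, padding=8.0)
        integral = float(dmap.grid.sum()) * dmap.voxel_volume
        expected = m.atomic_numbers().sum() * gaussian_integral(res)
        assert integral == pytest.approx(expected, rel=0.01)

    def test_translation_equivariance_by_one_voxel(self):
        m = make_toy_protein("beta-sandwich", 15, seed=1)
        a = simulate_map(m, 6.0, voxel=2.0, padding=10.0)
        b = simulate_map(m.translated(np.array([2.0, 0.0, 0.0])), 6.0,
                         like=a)
        assert np.allclose(b.grid[1:], a.grid[:-1], atol=1e-6)

    def test_undersampled_resolution_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            simulate_map(_carbon_at((0, 0, 0)), resolution=1.5, voxel=1.0)


class TestLowpass:
    def test_nyquist_filter_barely_touches_smooth_map(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        dmap = simulate_map(m, 8.0, voxel=1.0, padding=8.0)
        filt = lowpass(dmap, 2.0)  # cutoff at Nyquist of the 1 Å grid
        rms = float(np.sqrt(np.mean((filt.grid - dmap.grid) ** 2)))
        assert rms < 1e-6 * float(np.abs(dmap.grid).max())

    def test_reduces_white_noise_variance_and_keeps_mean(self):
        rng = np.random.default_rng(3)
        dmap = DensityMap(rng.normal(size=(24, 24, 24)).astype(np.float32), 1.0)
        filt = lowpass(dmap, 6.0)
        assert filt.grid.var() < 0.5 * dmap.grid.var()
        assert float(filt.grid.mean()) == pytest.approx(
            float(dmap.grid.mean()), abs=1e-6)

    def test_single_frequency_attenuated_by_filter_formula(self):
        # a pure cosine mode is an eigenvector of the filter: its amplitude
        # must scale by exactly the closed-form cosine-edge gain
        n, voxel = 32, 1.0
        for k in (3, 6, 9, 12):
            f = k / (n * voxel)
            x = np.arange(n) * voxel
            grid = np.broadcast_to(
                np.cos(2 * np.pi * f * x)[:, None, None], (n, n, n)).copy()
            dmap = DensityMap(grid.astype(np.float32), voxel)
            res = 4.0
            filt = lowpass(dmap, res)
            expected = cosine_edge_gain(f, res)
            got = (filt.grid[:, 0, 0] @ np.cos(2 * np.pi * f * x)) / \
                (grid[:, 0, 0] @ np.cos(2 * np.pi * f * x))
            assert got == pytest.approx(expected, abs=1e-5)


def _two_blob_map(gap=40.0, bridge=False):
    """Two compact Gaussian blobs (stacked atoms), optionally joined by a
    thin line of atoms whose density stays below the blob half-max."""
    rows = []
    for bx, ch in ((0.0, "A"), (gap, "B")):
        for k in range(3):  # 3 co-located carbons -> one tall Gaussian
            rows.append((ch, k + 1, "ALA", "CA", "C", (bx, 0.0, 0.0), 90.0))
    if bridge:
        for i, x in enumerate(np.arange(4.0, gap - 3.0, 3.0)):
            rows.append(("L", i + 1, "ALA", "CA", "C", (x, 0.0, 0.0), 90.0))
    model = build_model(rows)
    return simulate_map(model, 6.0, voxel=2.0, padding=8.0), model


class TestSegment:
    def test_two_blobs_at_half_max_threshold(self):
        dmap, _ = _two_blob_map()
        subs = segment_map(dmap, 0.5 * float(dmap.grid.max()))
        assert len(subs) == 2
        assert subs[0].volume >= subs[1].volume  # sorted by volume

    def test_threshold_above_max_gives_empty_list_with_warning(self):
        dmap, _ = _two_blob_map()
        with pytest.warns(UserWarning, match="maximum"):
            subs = segment_map(dmap, float(dmap.grid.max()) * 2.0)
        assert subs == []

    def test_bridged_blobs_connected_vs_watershed(self):
        dmap, _ = _two_blob_map(bridge=True)
        # below the bridge density: one 26-connected component, but the
        # watershed still splits it at the saddle between the two maxima
        thr = 0.1 * float(dmap.grid.max())
        joined = segment_map(dmap, thr, method="connected")
        split = segment_map(dmap, thr, method="watershed")
        assert len(joined) == 1
        assert len(split) >= 2

    def test_masks_pairwise_disjoint(self):
        dmap, _ = _two_blob_map(bridge=True)
        subs = segment_map(dmap, 0.3 * float(dmap.grid.max()),
                           method="watershed")
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                assert not (subs[i].mask & subs[j].mask).any()

    def test_min_volume_drops_speckle(self):
        dmap, _ = _two_blob_map()
        small = segment_map(dmap, 0.5 * float(dmap.grid.max()),
                            min_volume=1e6)
        assert small == []


class TestSubtract:
    def test_subtracting_the_only_blob_leaves_little_density(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        dmap = simulate_map(m, 6.0, voxel=2.0, padding=8.0)
        residual = subtract_fitted(dmap, [(m, Pose.identity())],
                                   mask_radius=4.0, soft_edge=3.0)
        assert np.sqrt(np.mean(residual.grid ** 2)) \
            < 0.05 * np.sqrt(np.mean(dmap.grid ** 2))

    def test_empty_placements_identity(self):
        dmap, _ = _two_blob_map()
        out = subtract_fitted(dmap, [])
        assert np.array_equal(out.grid, dmap.grid)

    def test_monotone_on_nonnegative_maps(self):
        dmap, model = _two_blob_map()
        out = subtract_fitted(dmap, [(model, Pose.identity())],
                              mask_radius=3.0, soft_edge=3.0)
        assert np.all(out.grid <= dmap.grid + 1e-6)
        # voxels far from any atom untouched
        far = dmap.grid.copy()
        far_mask = out.grid == dmap.grid
        assert far_mask.any()
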