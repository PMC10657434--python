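"""Docking: CC scoring, FFT translation search, pose recovery, validation."""

import numpy as np
import pytest

from capsfit.dock import (DockParams, _pose_rmsd, best_shift, cc_score,
                          exhaustive_dock, per_residue_cc, rotation_grid,
                          translation_search)
from capsfit.fixtures import (SceneSpec, make_scene, make_toy_protein,
                              random_pose)
from capsfit.helix import apply_cn
from capsfit.rigid import Pose, rotation_about_axis
from capsfit.voldens import SubMap, simulate_map

PARAMS = DockParams(scoring_resolution=6.0)


def _self_map(model, voxel=2.0):
    return simulate_map(model, 6.0, voxel=voxel, padding=8.0)


class TestCcScore:
    def test_perfect_match_scores_one(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        dmap = _self_map(m)
        assert cc_score(dmap, m, Pose.identity(), PARAMS) \
            == pytest.approx(1.0, abs=1e-6)

    def test_negated_map_scores_minus_one(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        dmap = _self_map(m)
        dmap.grid = -dmap.grid
        assert cc_score(dmap, m, Pose.identity(), PARAMS) \
            == pytest.approx(-1.0, abs=1e-6)

    def test_unrelated_blob_scores_low(self):
        m = make_toy_protein("helix-bundle", 25, seed=0)
        other = make_toy_protein("random-coil", 25, seed=5)
        dmap = _self_map(other)
        assert abs(cc_score(dmap, m, Pose.identity(), PARAMS)) < 0.3

    def test_no_overlap_scores_sentinel_with_warning(self):
        m = make_toy_protein("helix-bundle", 15, seed=0)
        dmap = _self_map(m)
        away = Pose(np.eye(3), np.array([500.0, 0.0, 0.0]))
        with pytest.warns(UserWarning):
            assert cc_score(dmap, m, away, PARAMS) == -1.0

    def test_invariant_under_common_rigid_transform(self):
        from scipy.ndimage import map_coordinates
        m = make_toy_protein("beta-sandwich", 20, seed=2)
        dmap = _self_map(m)
        base = cc_score(dmap, m, Pose.identity(), PARAMS)
        T = Pose(rotation_about_axis(np.array([0.3, 1.0, 0.2]), 25.0),
                 np.array([3.0, -2.0, 1.0]))
        moved = m.transformed(T.rotation, T.translation)
        # resample the map under the same transform: value at world x of the
        # new map = value at T^-1 x of the old map
        idx = np.indices(dmap.grid.shape).reshape(3, -1).T.astype(float)
        world = dmap.voxel_to_world(idx)
        src = T.inverse().apply(world)
        src_vox = dmap.world_to_voxel(src)
        resampled = map_coordinates(dmap.grid.astype(float), src_vox.T,
                                    order=3, mode="constant", cval=0.0
                                    ).reshape(dmap.grid.shape)
        moved_map = dmap.copy()
        moved_map.grid = resampled.astype(np.float32)
        got = cc_score(moved_map, moved, Pose.identity(), PARAMS)
        assert got == pytest.approx(base, abs=0.02)


class TestTranslationSearch:
    def test_fft_equals_direct_scan_on_random_grids(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(6, 7, 5))
        t = rng.normal(size=(6, 7, 5))
        fft = translation_search(e, t, "fft")
        direct = translation_search(e, t, "direct")
        assert np.allclose(fft, direct, atol=1e-9)
        assert best_shift(fft) == best_shift(direct)

    def test_shift_recovers_planted_translation(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(12, 12, 12)) ** 2
        e = np.roll(t, (3, -2, 1), axis=(0, 1, 2))
        assert best_shift(translation_search(e, t)) == (3, -2, 1)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            translation_search(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


class TestRotationGrid:
    def test_contains_identity_and_is_deterministic(self):
        grid = rotation_grid(30.0)
        assert any(np.allclose(R, np.eye(3), atol=1e-12) for R in grid)
        again = rotation_grid(30.0)
        assert all(np.array_equal(a, b) for a, b in zip(grid, again))

    def test_finer_step_gives_more_rotations(self):
        assert len(rotation_grid(12.0)) > len(rotation_grid(30.0)) \
            > len(rotation_grid(60.0))

    def test_all_entries_are_proper_rotations(self):
        for R in rotation_grid(45.0):
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def _single_fragment_scene(seed=3):
    model = make_toy_protein("helix-bundle", 30, seed=seed)
    pose = random_pose(np.random.default_rng(seed))
    spec = SceneSpec(models={"frag": model}, placements=[("frag", pose)],
                     decoy_pool_size=0, seed=seed, voxel=2.0)
    dmap, truth = make_scene(spec)
    submap = SubMap(dmap, dmap.grid > 0.15 * float(dmap.grid.max()), "scene")
    return model, pose, submap


class TestExhaustiveDock:
    def test_recovers_planted_pose_within_tolerance(self):
        model, pose, submap = _single_fragment_scene()
        params = DockParams(angular_step=30.0, top_n=3, refine=True,
                            scoring_resolution=6.0, lowpass_template=True)
        fits = exhaustive_dock(model, submap, params)
        best = fits[0]
        # translation error of the placed centroid
        c = model.centroid()
        dt = np.linalg.norm(best.pose.apply(c) - pose.apply(c))
        # rotation error angle
        dR = best.pose.rotation @ pose.rotation.T
        ang = np.rad2deg(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1)))
        assert dt <= 2.0
        assert ang <= 5.0
        assert best.cc > 0.85

    def test_wrong_fold_decoy_ranks_below_true_fragment(self):
        model, pose, submap = _single_fragment_scene()
        decoy = make_toy_protein("beta-sandwich", 30, seed=11)
        params = DockParams(angular_step=45.0, top_n=2, refine=True,
                            scoring_resolution=6.0, lowpass_template=True)
        true_cc = exhaustive_dock(model, submap, params)[0].cc
        decoy_cc = exhaustive_dock(decoy, submap, params)[0].cc
        assert decoy_cc < true_cc

    def test_ranking_is_deterministic(self):
        model, _, submap = _single_fragment_scene()
        params = DockParams(angular_step=60.0, top_n=5,
                            scoring_resolution=6.0)
        a = exhaustive_dock(model, submap, params)
        b = exhaustive_dock(model, submap, params)
        assert [f.cc for f in a] == [f.cc for f in b]
        assert all(np.array_equal(x.pose.as_flat(), y.pose.as_flat())
                   for x, y in zip(a, b))
        assert [f.rank for f in a] == list(range(1, len(a) + 1))

    def test_c2_symmetric_poses_deduplicate(self):
        unit = make_toy_protein("helix-bundle", 14, seed=4).translated(
            np.array([8.0, 0.0, 0.0]))
        dimer = apply_cn(unit, 2)
        dimer = dimer.translated(-dimer.centroid())
        # the C2 partner pose places the same point cloud
        c2 = Pose(rotation_about_axis(np.array([0.0, 0.0, 1.0]), 180.0),
                  np.zeros(3))
        n_ref = min(dimer.n_atoms, 50)
        ref = dimer.xyz[np.linspace(0, dimer.n_atoms - 1, n_ref).astype(int)]
        # chamfer distance sees the C2 partner as (nearly) the same placement,
        # well inside the dedup cutoff — index-wise RMSD would be ~2x the
        # dimer radius
        assert _pose_rmsd(Pose.identity(), c2, ref) < 2.0
        dmap = _self_map(dimer)
        submap = SubMap(dmap, dmap.grid > 0.1 * float(dmap.grid.max()), "d")
        params = DockParams(angular_step=45.0, top_n=4,
                            scoring_resolution=6.0, dedup_rmsd=3.0)
        fits = exhaustive_dock(dimer, submap, params)
        # surviving poses are pairwise distinct placements of the cloud
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                assert _pose_rmsd(fits[i].pose, fits[j].pose, ref) \
                    >= params.dedup_rmsd


class TestRecovery:
    def test_true_fragment_outranks_decoys_across_seeded_scenes(self):
        """Over 20 seeded scenes (1 true fragment + 5 decoys) the true
        candidate ranks first in at least 19."""
        from capsfit.assign import dock_pool_into_submap
        from capsfit.pool import build_pool
        from capsfit.voldens import segment_map

        params = DockParams(angular_step=60.0, top_n=6,
                            scoring_resolution=6.0, lowpass_template=True)
        rng = np.random.default_rng(314)
        wins = 0
        for _ in range(20):
            seed = int(rng.integers(0, 2 ** 31 - 1))
            scene_rng = np.random.default_rng(seed)
            kinds = ["helix-bundle", "beta-sandwich", "random-coil"]
            true = make_toy_protein(kinds[seed % 3], 34,
                                    seed=int(scene_rng.integers(2 ** 31)))
            spec = SceneSpec(models={"true": true},
                             placements=[("true",
                                          random_pose(scene_rng))],
                             decoy_pool_size=5, seed=seed, voxel=2.5)
            dmap, truth = make_scene(spec)
            subs = segment_map(dmap, 0.25 * float(dmap.grid.max()),
                               min_volume=800.0)
            sub = max(subs, key=lambda s: s.n_voxels).cropped(8.0)
            sources = truth.all_sources()
            pool = build_pool(list(sources.values()), round="full",
                              source_ids=list(sources))
            fits = dock_pool_into_submap(pool, sub, params, refine_top=3)
            if fits[0].source_id == "true":
                wins += 1
        assert wins >= 19


class TestPerResidueCC:
    def test_perfect_map_gives_uniformly_high_cc(self):
        m = make_toy_protein("helix-bundle", 20, seed=0)
        dmap = _self_map(m, voxel=1.5)
        table = per_residue_cc(m, dmap, PARAMS)
        assert len(table) == 20
        assert (table["cc"] >= 0.99).all()

    def test_displaced_residue_has_minimum_cc(self):
        from conftest import build_model
        # straight CA chain: a displaced residue lands in empty density
        m = build_model([("A", i + 1, "ALA", "CA", "C",
                          (3.8 * i, 0.0, 0.0), 90.0) for i in range(20)])
        dmap = _self_map(m, voxel=1.5)
        bad = m.copy()
        bad.xyz = bad.xyz.copy()
        bad.xyz[bad.resnum == 10] += np.array([0.0, 5.0, 0.0])
        table = per_residue_cc(bad, dmap, PARAMS)
        worst = table.loc[table["cc"].idxmin()]
        assert worst["resnum"] == 10

    def test_band_flags_populated_on_graded_fixture(self):
        m = make_toy_protein("helix-bundle", 24, seed=1)
        dmap = _self_map(m, voxel=1.5)
        graded = m.copy()
        graded.xyz = graded.xyz.copy()
        # progressively displace three residues: mild, moderate, severe
        for resnum, shift in ((5, 1.0), (12, 2.5), (20, 6.0)):
            graded.xyz[graded.resnum == resnum] += np.array([shift, 0.0, 0.0])
        table = per_residue_cc(graded, dmap, PARAMS).set_index("resnum")
        assert bool(table.loc[20, "below_0.5"])
        assert bool(table.loc[12, "below_0.7"])
        assert not bool(table.loc[5, "below_0.5"])
        # flags must agree with the reported cc values
        assert ((table["cc"] < 0.7) == table["below_0.7"]).all()
        assert ((table["cc"] < 0.5) == table["below_0.5"]).all()
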