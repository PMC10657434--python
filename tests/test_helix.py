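"""Helical lattice generation/recovery and rotational-order detection."""

import numpy as np
import pytest

from capsfit.fixtures import make_toy_protein
from capsfit.helix import (AmbiguousLatticeError, HelicalParams,
                           NoSymmetrySignalError, apply_cn, apply_helical,
                           detect_rotational_order, estimate_helical_params)
from capsfit.structio import DensityMap
from capsfit.voldens import simulate_map

#: lattice parameters of the studied nucleocapsid cylinder
CAPSID_RISE = 44.1
CAPSID_TWIST = 18.5
CAPSID_START = 14


def _unit(seed=0, length=12, offset=60.0):
    """Small off-axis unit so screw parameters are well-determined."""
    m = make_toy_protein("helix-bundle", length, seed=seed)
    return m.translated(np.array([offset, 0.0, 0.0]))


def _chain_groups(unit, assembly, n_copies):
    """Chain-name groups per copy as produced by apply_helical/apply_cn."""
    per_copy = len(set(map(str, unit.chain)))
    names = list(dict.fromkeys(map(str, assembly.chain)))
    assert len(names) == per_copy * n_copies
    return [names[i * per_copy:(i + 1) * per_copy] for i in range(n_copies)]


class TestApplyHelical:
    def test_single_start_single_ring_is_identity(self):
        unit = _unit()
        asm = apply_helical(unit, HelicalParams(rise=40.0, twist=20.0), 1)
        assert asm.n_atoms == unit.n_atoms
        assert np.allclose(asm.xyz, unit.xyz)

    def test_capsid_lattice_copy_count_and_axial_rise(self):
        unit = _unit()
        params = HelicalParams(rise=CAPSID_RISE, twist=CAPSID_TWIST,
                               start=CAPSID_START)
        asm = apply_helical(unit, params, n_rings=2)
        assert asm.n_atoms == unit.n_atoms * CAPSID_START * 2
        groups = _chain_groups(unit, asm, CAPSID_START * 2)
        # copy k of ring 1 sits exactly one rise above its ring-0 partner
        for k in range(CAPSID_START):
            ring0 = asm.select(np.isin(asm.chain.astype(str), groups[k]))
            ring1 = asm.select(np.isin(asm.chain.astype(str),
                                       groups[CAPSID_START + k]))
            dz = ring1.xyz[:, 2] - ring0.xyz[:, 2]
            assert np.allclose(dz, CAPSID_RISE, atol=1e-9)

    def test_negative_twist_mirrors_the_lattice(self):
        unit = _unit()
        plus = apply_helical(unit, HelicalParams(rise=30.0, twist=25.0), 2)
        minus = apply_helical(
            unit.transformed(np.diag([1.0, -1.0, 1.0]), np.zeros(3)),
            HelicalParams(rise=30.0, twist=-25.0), 2)
        # mirroring the unit through the xz-plane and negating the twist
        # reproduces the mirrored assembly (handedness convention)
        assert np.allclose(minus.xyz, plus.xyz * np.array([1.0, -1.0, 1.0]),
                           atol=1e-9)


class TestEstimate:
    def test_round_trip_on_capsid_parameters_is_exact(self):
        unit = _unit()
        params = HelicalParams(rise=CAPSID_RISE, twist=CAPSID_TWIST,
                               start=CAPSID_START)
        asm = apply_helical(unit, params, n_rings=3)
        groups = _chain_groups(unit, asm, CAPSID_START * 3)
        got = estimate_helical_params(asm, groups[0], groups[CAPSID_START],
                                      ring_neighbor_chains=groups[1])
        assert got.rise == pytest.approx(CAPSID_RISE, abs=1e-6)
        assert got.twist == pytest.approx(CAPSID_TWIST, abs=1e-6)
        assert got.start == CAPSID_START

    def test_randomised_round_trips_recover_exactly(self):
        rng = np.random.default_rng(2024)
        unit = _unit()
        failures = 0
        for _ in range(100):
            rise = float(rng.uniform(20.0, 60.0))
            twist = float(rng.uniform(-40.0, 40.0))
            asm = apply_helical(unit, HelicalParams(rise=rise, twist=twist), 2)
            groups = _chain_groups(unit, asm, 2)
            got = estimate_helical_params(asm, groups[0], groups[1])
            if abs(got.rise - rise) > 1e-6 or abs(got.twist - twist) > 1e-6:
                failures += 1
        assert failures == 0

    def test_noisy_units_recover_rise_within_tenth_angstrom(self):
        rng = np.random.default_rng(7)
        unit = _unit(length=120, offset=20.0)
        asm = apply_helical(unit, HelicalParams(rise=CAPSID_RISE,
                                                twist=CAPSID_TWIST), 3)
        noisy = asm.copy()
        noisy.xyz = asm.xyz + rng.normal(0.0, 0.3, size=asm.xyz.shape)
        groups = _chain_groups(unit, noisy, 3)
        got = estimate_helical_params(noisy, groups[0],
                                      [groups[1], groups[2]])
        assert got.rise == pytest.approx(CAPSID_RISE, abs=0.1)

    def test_unrelated_units_raise_ambiguous_lattice(self):
        a = _unit(seed=1, length=20)
        b = make_toy_protein("random-coil", 20, seed=9, chain="Z").translated(
            np.array([80.0, 0.0, 40.0]))
        from capsfit.structio import AtomicModel
        asm = AtomicModel.concatenate([a, b])
        with pytest.raises(AmbiguousLatticeError):
            estimate_helical_params(asm, ["A"], ["Z"])


class TestApplyCn:
    def test_order_one_is_identity(self):
        unit = _unit()
        asm = apply_cn(unit, 1)
        assert np.allclose(asm.xyz, unit.xyz)

    def test_c14_generator_closes_the_group(self):
        from capsfit.rigid import rotation_about_axis
        g = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 360.0 / 14)
        acc = np.eye(3)
        for _ in range(14):
            acc = g @ acc
        assert np.allclose(acc, np.eye(3), atol=1e-9)
        asm = apply_cn(_unit(), 14)
        assert asm.n_atoms == _unit().n_atoms * 14

    def test_copies_preserve_axis_distance(self):
        unit = _unit()
        asm = apply_cn(unit, 7)
        r = np.linalg.norm(asm.xyz[:, :2], axis=1)
        assert np.allclose(sorted(r[:unit.n_atoms]),
                           sorted(r[-unit.n_atoms:]), atol=1e-9)


def _ring_map(order, seed=0, inner=None, voxel=3.0, resolution=7.0):
    unit = make_toy_protein("helix-bundle", 16, seed=seed).translated(
        np.array([45.0, 0.0, 0.0]))
    ring = apply_cn(unit, order)
    parts = [ring]
    if inner:
        inner_unit = make_toy_protein("beta-sandwich", 14, seed=seed + 1)\
            .translated(np.array([12.0, 0.0, 0.0]))
        parts.append(apply_cn(inner_unit, inner))
    from capsfit.structio import AtomicModel
    return simulate_map(AtomicModel.concatenate(parts), resolution,
                        voxel=voxel, padding=8.0)


class TestRotationalOrder:
    def test_c7_ring_detected(self):
        assert detect_rotational_order(_ring_map(7), range(2, 17)) == 7

    def test_c14_ring_detected(self):
        assert detect_rotational_order(_ring_map(14), range(2, 17)) == 14

    def test_spherical_blob_raises_no_signal(self):
        from conftest import build_model
        blob = build_model([("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0), 90.0)])
        dmap = simulate_map(blob, 12.0, voxel=3.0, padding=15.0)
        with pytest.raises(NoSymmetrySignalError):
            detect_rotational_order(dmap, range(2, 13))

    def test_flat_map_raises_no_signal(self):
        dmap = DensityMap(np.zeros((10, 10, 10), np.float32), 2.0)
        with pytest.raises(NoSymmetrySignalError):
            detect_rotational_order(dmap, range(2, 9))
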