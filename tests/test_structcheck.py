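"""Geometric screens: disulfides, cross-link candidates, polar contacts."""

import numpy as np
import pytest

from capsfit.structcheck import (ContactParams, find_disulfides,
                                 find_polar_contacts, predict_crosslinks)

from conftest import build_model


def _cys(chain, resnum, sg_xyz):
    return [(chain, resnum, "CYS", "CB", "C",
             (sg_xyz[0] - 1.0, sg_xyz[1], sg_xyz[2]), 90.0),
            (chain, resnum, "CYS", "SG", "S", tuple(sg_xyz), 90.0)]


def _lys(chain, resnum, nz_xyz):
    return [(chain, resnum, "LYS", "CA", "C",
             (nz_xyz[0] - 2.0, nz_xyz[1], nz_xyz[2]), 90.0),
            (chain, resnum, "LYS", "NZ", "N", tuple(nz_xyz), 90.0)]


class TestDisulfides:
    def test_bonded_pair_detected(self, cys_pair_model):
        bonds = find_disulfides(cys_pair_model)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05)

    def test_distant_pair_not_detected(self):
        m = build_model(_cys("A", 1, (0, 0, 0)) + _cys("B", 1, (4.0, 0, 0)))
        assert find_disulfides(m) == []

    def test_cys_without_sg_skipped_with_warning(self):
        rows = _cys("A", 1, (0, 0, 0)) + [
            ("B", 1, "CYS", "CB", "C", (2.0, 0.0, 0.0), 90.0)]
        with pytest.warns(UserWarning, match="SG"):
            bonds = find_disulfides(build_model(rows))
        assert bonds == []

    def test_sorted_by_distance_and_deduplicated(self):
        m = build_model(_cys("A", 1, (0, 0, 0)) + _cys("B", 1, (2.3, 0, 0))
                        + _cys("C", 1, (-2.0, 0, 0)))
        bonds = find_disulfides(m)
        assert [b.distance for b in bonds] == sorted(b.distance for b in bonds)
        pairs = {frozenset([(b.a.chain, b.a.resnum), (b.b.chain, b.b.resnum)])
                 for b in bonds}
        assert len(pairs) == len(bonds)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        rows = []
        for i, ch in enumerate("ABCDEF"):
            rows += _cys(ch, 1, rng.uniform(-4, 4, size=3))
        m = build_model(rows)
        counts = [len(find_disulfides(m, ContactParams(disulfide_cutoff=c)))
                  for c in (1.0, 2.0, 3.0, 5.0, 8.0)]
        assert counts == sorted(counts)


class TestCrosslinks:
    def test_classification_bands(self):
        for dist, expected in ((12.0, "within-range"), (9.0, "below-min"),
                               (15.5, "above-max")):
            m = build_model(_lys("A", 1, (0, 0, 0)) + _lys("B", 1, (dist, 0, 0)))
            cands = predict_crosslinks(m, include_n_termini=False)
            assert len(cands) == 1
            assert cands[0].classification == expected
            assert cands[0].distance == pytest.approx(dist)
        within = [c for c in cands if c.classification == "within-range"]
        assert within == []  # the 15.5 Å pair does not count as predicted

    def test_nz_to_nz_distance_not_calpha(self):
        m = build_model(_lys("A", 1, (0, 0, 0)) + _lys("B", 1, (12.0, 0, 0)))
        cands = predict_crosslinks(m, include_n_termini=False)
        # CA atoms are 2 Å offset; the reported distance must be NZ-NZ
        assert cands[0].distance == pytest.approx(12.0, abs=1e-9)

    def test_n_terminal_amines_included_by_default(self):
        rows = _lys("A", 5, (0, 0, 0))
        rows += [("B", 1, "GLY", "N", "N", (11.0, 0.0, 0.0), 90.0),
                 ("B", 1, "GLY", "CA", "C", (12.0, 1.0, 0.0), 90.0)]
        with_nt = predict_crosslinks(build_model(rows))
        without = predict_crosslinks(build_model(rows), include_n_termini=False)
        assert any(c.amine_kind[1] == "N-terminus" for c in with_nt)
        assert len(without) == 0

    def test_intra_vs_inter_chain_labels(self):
        m = build_model(_lys("A", 1, (0, 0, 0)) + _lys("A", 9, (12, 0, 0))
                        + _lys("B", 1, (0, 12, 0)))
        cands = predict_crosslinks(m, include_n_termini=False)
        flags = {(c.a.resnum, c.b.resnum, c.a.chain == c.b.chain)
                 for c in cands}
        assert (1, 9, True) in flags

    def test_burial_filter_drops_occluded_amine(self):
        rows = _lys("A", 1, (0, 0, 0)) + _lys("B", 1, (12.0, 0, 0))
        # bury the first NZ under a shell of neighbours
        rng = np.random.default_rng(0)
        for i in range(60):
            p = rng.normal(0, 3.0, size=3)
            rows.append(("C", i + 1, "ALA", "CA", "C", tuple(p), 90.0))
        m = build_model(rows)
        open_links = predict_crosslinks(m, include_n_termini=False)
        filtered = predict_crosslinks(m, include_n_termini=False,
                                      max_neighbor_count=30)
        assert len(open_links) >= 1
        assert len(filtered) == 0

    def test_restraint_list_exports_within_range_pairs_only(self):
        from capsfit.structcheck import restraint_list
        m = build_model(_lys("A", 1, (0, 0, 0)) + _lys("B", 1, (12.0, 0, 0))
                        + _lys("C", 1, (0, 22.0, 0)))
        cands = predict_crosslinks(m, include_n_termini=False)
        table = restraint_list(cands)
        assert len(table) == 1
        assert table.iloc[0]["lower_A"] == 10.0
        assert table.iloc[0]["upper_A"] == 15.0

    def test_monotone_in_range_width(self):
        rng = np.random.default_rng(9)
        rows = []
        for i, ch in enumerate("ABCDEFGH"):
            rows += _lys(ch, 1, rng.uniform(-12, 12, size=3))
        m = build_model(rows)
        counts = []
        for hi in (11.0, 13.0, 15.0, 18.0):
            cands = predict_crosslinks(m, ContactParams(crosslink_range=(10.0, hi)),
                                       include_n_termini=False)
            counts.append(sum(1 for c in cands
                              if c.classification == "within-range"))
        assert counts == sorted(counts)


def _beta_pair():
    """Two idealised antiparallel 4-residue strands, backbone N/O only.

    Strand A: N at x=0,3.5,7,10.5 (y=0); strand B: O directly across at
    y=2.9 — four N...O pairs at 2.9 Å by construction.
    """
    rows_a, rows_b = [], []
    for i in range(4):
        x = 3.5 * i
        rows_a.append(("A", i + 1, "GLY", "N", "N", (x, 0.0, 0.0), 90.0))
        rows_a.append(("A", i + 1, "GLY", "CA", "C", (x + 1.0, 0.5, 0.0), 90.0))
        rows_b.append(("B", i + 1, "GLY", "O", "O", (x, 2.9, 0.0), 90.0))
        rows_b.append(("B", i + 1, "GLY", "CA", "C", (x - 1.0, 3.4, 0.0), 90.0))
    return build_model(rows_a), build_model(rows_b)


class TestPolarContacts:
    def test_beta_pair_backbone_hbond_count_matches_hand_enumeration(self):
        a, b = _beta_pair()
        with pytest.warns(UserWarning, match="hydrogens"):
            contacts = find_polar_contacts(a, b)
        hbonds = [c for c in contacts if c.kind == "hydrogen-bond"]
        assert len(hbonds) == 4  # one N...O pair per residue, 2.9 Å each
        assert all(c.distance == pytest.approx(2.9) for c in hbonds)

    def test_lys_glu_salt_bridge(self):
        lys = build_model(_lys("A", 1, (0, 0, 0)))
        glu = build_model([
            ("B", 7, "GLU", "CD", "C", (4.0, 0.0, 0.0), 90.0),
            ("B", 7, "GLU", "OE1", "O", (3.2, 0.0, 0.0), 90.0)])
        with pytest.warns(UserWarning):
            contacts = find_polar_contacts(lys, glu)
        salts = [c for c in contacts if c.kind == "salt-bridge"]
        assert len(salts) == 1
        assert salts[0].distance == pytest.approx(3.2)

    def test_separated_models_have_no_contacts(self):
        a, b = _beta_pair()
        far = b.translated(np.array([0.0, 10.0, 0.0]))
        with pytest.warns(UserWarning):
            assert find_polar_contacts(a, far) == []

    def test_symmetric_in_argument_order(self):
        a, b = _beta_pair()
        with pytest.warns(UserWarning):
            ab = find_polar_contacts(a, b)
            ba = find_polar_contacts(b, a)
        key = lambda c: (c.kind, round(c.distance, 6))
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_distances_recomputable_from_coordinates(self):
        a, b = _beta_pair()
        with pytest.warns(UserWarning):
            contacts = find_polar_contacts(a, b)
        for c in contacts:
            da = a if c.donor.chain == "A" else b
            ac = b if c.acceptor.chain == "B" else a
            dsel = (da.chain.astype(str) == c.donor.chain) \
                & (da.resnum == c.donor.resnum) & (da.atname == c.donor_atom)
            asel = (ac.chain.astype(str) == c.acceptor.chain) \
                & (ac.resnum == c.acceptor.resnum) \
                & (ac.atname == c.acceptor_atom)
            d = np.linalg.norm(da.xyz[dsel][0] - ac.xyz[asel][0])
            assert d == pytest.approx(c.distance, abs=1e-6)
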