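"""Shared fixtures: tiny hand-built models and maps, all generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from capsfit.structio import AtomicModel


def build_model(rows: list[tuple]) -> AtomicModel:
    """Build an AtomicModel from (chain, resnum, resname, atname, element,
    xyz, confidence) tuples; occupancy fixed at 1."""
    cols = list(zip(*rows))
    return AtomicModel(
        chain=np.array(cols[0], object),
        resnum=np.array(cols[1], int),
        resname=np.array(cols[2], object),
        atname=np.array(cols[3], object),
        element=np.array(cols[4], object),
        xyz=np.array(cols[5], float),
        confidence=np.array(cols[6], float),
        occupancy=np.ones(len(rows)),
    )


@pytest.fixture
def one_atom_model() -> AtomicModel:
    return build_model([("A", 1, "ALA", "CA", "C", (1.5, 2.5, 3.5), 87.6)])


@pytest.fixture
def tri_residue_model() -> AtomicModel:
    """Three CA-only residues with mixed confidence around the trim threshold."""
    return build_model([
        ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0), 90.0),
        ("A", 2, "GLY", "CA", "C", (3.8, 0.0, 0.0), 69.9),
        ("A", 3, "SER", "CA", "C", (7.6, 0.0, 0.0), 70.0),
    ])


@pytest.fixture
def cys_pair_model() -> AtomicModel:
    """Two cysteines with SG atoms 2.05 Å apart (a disulfide)."""
    return build_model([
        ("A", 10, "CYS", "CB", "C", (0.0, 0.0, 0.0), 90.0),
        ("A", 10, "CYS", "SG", "S", (1.0, 0.0, 0.0), 90.0),
        ("B", 10, "CYS", "CB", "C", (4.0, 0.0, 0.0), 90.0),
        ("B", 10, "CYS", "SG", "S", (3.05, 0.0, 0.0), 90.0),
    ])
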