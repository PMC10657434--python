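"""Geometric screens on assembled models.

Three screens recur when validating capsid assemblies:

* disulfide bonds — cysteine pairs whose Sγ atoms come within bonding
  distance (default 2.5 Å detection cutoff);
* chemical cross-link candidates — lysine side-chain amines (NZ) and,
  optionally, protein N-terminal amines whose separation falls inside the
  reactive range of an amine-reactive linker such as BS³ (11.4 Å spacer;
  practical range 10–15 Å between amine nitrogens);
* polar contacts at interfaces — hydrogen-bond donor/acceptor pairs and
  salt bridges between opposite-charge side-chain groups.

Distances are measured between the chemically relevant atoms (Sγ–Sγ,
NZ–NZ), not Cα positions. All reported distances are recomputable from the
coordinates to float precision.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import AtomicModel

__all__ = [
    "ContactParams",
    "DisulfideBond",
    "CrossLinkCandidate",
    "PolarContact",
    "BS3_SPACER_LENGTH",
    "find_disulfides",
    "predict_crosslinks",
    "find_polar_contacts",
    "crosslink_table",
]

#: Spacer length (Å) of the BS3 amine-reactive cross-linker.
BS3_SPACER_LENGTH = 11.4


@dataclasses.dataclass(frozen=True)
class ContactParams:
    """Distance/angle criteria for the geometric screens."""

    disulfide_cutoff: float = 2.5  # Sγ–Sγ Å
    hbond_cutoff: float = 3.5  # donor–acceptor Å
    hbond_angle_min: float = 120.0  # D–H...A degrees, when H present
    salt_bridge_cutoff: float = 4.0  # charged-group N/O pair Å
    crosslink_range: tuple[float, float] = (10.0, 15.0)  # amine–amine Å

    def __post_init__(self) -> None:
        for name in ("disulfide_cutoff", "hbond_cutoff", "salt_bridge_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.crosslink_range
        if not (0 <= lo < hi):
            raise ValueError("cross-link range must satisfy 0 <= min < max")


@dataclasses.dataclass(frozen=True)
class ResidueRef:
    chain: str
    resnum: int
    resname: str = ""


@dataclasses.dataclass(frozen=True)
class DisulfideBond:
    a: ResidueRef
    b: ResidueRef
    distance: float  # Sγ–Sγ Å


@dataclasses.dataclass(frozen=True)
class CrossLinkCandidate:
    a: ResidueRef
    b: ResidueRef
    distance: float  # amine–amine Å
    classification: str  # within-range / below-min / above-max
    intra_chain: bool
    amine_kind: tuple[str, str] = ("NZ", "NZ")  # NZ or N-terminus per side


@dataclasses.dataclass(frozen=True)
class PolarContact:
    kind: str  # hydrogen-bond / salt-bridge
    donor: ResidueRef
    acceptor: ResidueRef
    donor_atom: str
    acceptor_atom: str
    distance: float


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------

def find_disulfides(model: AtomicModel,
                    params: ContactParams = ContactParams(),
                    ) -> list[DisulfideBond]:
    """All cysteine pairs with Sγ–Sγ distance within the detection cutoff.

    Pairs are deduplicated and sorted by distance. Cysteines lacking a
    modelled Sγ are skipped with a warning.
    """
    refs: list[ResidueRef] = []
    sg: list[np.ndarray] = []
    for ch, rn, idx in model.residues():
        resname = str(model.resname[idx[0]])
        if resname != "CYS":
            continue
        names = [str(a) for a in model.atname[idx]]
        if "SG" in names:
            sg.append(model.xyz[idx[names.index("SG")]])
            refs.append(ResidueRef(ch, rn, resname))
        else:
            warnings.warn(f"CYS {ch}/{rn} has no SG atom; skipped")
    if len(refs) < 2:
        return []
    d = cdist(np.array(sg), np.array(sg))
    bonds = []
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            if d[i, j] <= params.disulfide_cutoff:
                bonds.append(DisulfideBond(refs[i], refs[j], float(d[i, j])))
    bonds.sort(key=lambda b: b.distance)
    return bonds


# ---------------------------------------------------------------------------
# Cross-links
# ---------------------------------------------------------------------------

def _amine_sites(model: AtomicModel, include_n_termini: bool,
                 ) -> tuple[list[ResidueRef], np.ndarray, list[str]]:
    refs: list[ResidueRef] = []
    pos: list[np.ndarray] = []
    kinds: list[str] = []
    first_res: dict[str, int] = {}
    for ch, rn, _ in model.residues():
        first_res.setdefault(ch, rn)
        first_res[ch] = min(first_res[ch], rn)
    for ch, rn, idx in model.residues():
        resname = str(model.resname[idx[0]])
        names = [str(a) for a in model.atname[idx]]
        if resname == "LYS" and "NZ" in names:
            refs.append(ResidueRef(ch, rn, resname))
            pos.append(model.xyz[idx[names.index("NZ")]])
            kinds.append("NZ")
        if include_n_termini and rn == first_res[ch] and "N" in names:
            refs.append(ResidueRef(ch, rn, resname))
            pos.append(model.xyz[idx[names.index("N")]])
            kinds.append("N-terminus")
    return refs, (np.array(pos) if pos else np.empty((0, 3))), kinds


def _burial_counts(sites: np.ndarray, all_xyz: np.ndarray,
                   radius: float = 8.0) -> np.ndarray:
    """Neighbour-count burial proxy: atoms within ``radius`` Å of each site."""
    if len(sites) == 0:
        return np.empty(0)
    d = cdist(sites, all_xyz)
    return (d < radius).sum(axis=1)


def predict_crosslinks(models: Sequence[AtomicModel] | AtomicModel,
                       params: ContactParams = ContactParams(),
                       include_n_termini: bool = True,
                       max_neighbor_count: int | None = None,
                       ) -> list[CrossLinkCandidate]:
    """Enumerate amine–amine pairs and classify them against the linker range.

    ``models`` must already sit in one common frame; they are merged for the
    scan so inter- and intra-chain pairs are both reported (labelled).
    Pairs below the range minimum or above the maximum are classified but
    excluded from the within-range count. ``max_neighbor_count`` applies an
    approximate burial filter (sites with more neighbouring atoms than the
    cutoff within 8 Å are considered occluded and dropped).
    """
    if isinstance(models, AtomicModel):
        merged = models
    else:
        merged = AtomicModel.concatenate(
            [_prefix_chains(m, i) for i, m in enumerate(models)])
    refs, pos, kinds = _amine_sites(merged, include_n_termini)
    if len(refs) < 2:
        return []
    if max_neighbor_count is not None:
        counts = _burial_counts(pos, merged.xyz)
        keep = counts <= max_neighbor_count
        refs = [r for r, k in zip(refs, keep) if k]
        kinds = [k_ for k_, k in zip(kinds, keep) if k]
        pos = pos[keep]
    lo, hi = params.crosslink_range
    d = cdist(pos, pos)
    out = []
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            if refs[i] == refs[j]:
                continue
            dist = float(d[i, j])
            if dist < lo:
                cls = "below-min"
            elif dist > hi:
                cls = "above-max"
            else:
                cls = "within-range"
            if cls == "above-max" and dist > 2 * hi:
                continue  # far pairs are not interesting even as exclusions
            out.append(CrossLinkCandidate(
                refs[i], refs[j], dist, cls,
                intra_chain=refs[i].chain == refs[j].chain,
                amine_kind=(kinds[i], kinds[j])))
    out.sort(key=lambda c: c.distance)
    return out


def _prefix_chains(model: AtomicModel, index: int) -> AtomicModel:
    if index == 0:
        return model
    out = model.copy()
    out.chain = np.array([f"m{index}:{c}" for c in model.chain], dtype=object)
    return out


def crosslink_table(candidates: Sequence[CrossLinkCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chain_a": c.a.chain, "res_a": c.a.resnum, "kind_a": c.amine_kind[0],
        "chain_b": c.b.chain, "res_b": c.b.resnum, "kind_b": c.amine_kind[1],
        "distance_A": c.distance, "classification": c.classification,
        "intra_chain": c.intra_chain} for c in candidates])


def restraint_list(candidates: Sequence[CrossLinkCandidate],
                   params: ContactParams = ContactParams()) -> pd.DataFrame:
    """Within-range candidates as a simple distance-restraint table."""
    lo, hi = params.crosslink_range
    rows = [{"chain_a": c.a.chain, "res_a": c.a.resnum,
             "chain_b": c.b.chain, "res_b": c.b.resnum,
             "lower_A": lo, "upper_A": hi}
            for c in candidates if c.classification == "within-range"]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Polar contacts
# ---------------------------------------------------------------------------

# side-chain donor / acceptor atoms by residue (backbone handled separately)
_SC_DONORS = {
    "ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"],
    "ASN": ["ND2"], "GLN": ["NE2"], "SER": ["OG"], "THR": ["OG1"],
    "TYR": ["OH"], "TRP": ["NE1"], "CYS": ["SG"],
}
_SC_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
}
_POSITIVE = {"ARG": ["NH1", "NH2", "NE"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
_NEGATIVE = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


def _polar_atoms(model: AtomicModel, table: dict[str, list[str]],
                 backbone: str | None) -> tuple[list[ResidueRef], list[str], np.ndarray]:
    refs, names, pos = [], [], []
    for ch, rn, idx in model.residues():
        resname = str(model.resname[idx[0]])
        atnames = [str(a) for a in model.atname[idx]]
        wanted = list(table.get(resname, []))
        if backbone and backbone in atnames:
            wanted.append(backbone)
        for w in wanted:
            if w in atnames:
                refs.append(ResidueRef(ch, rn, resname))
                names.append(w)
                pos.append(model.xyz[idx[atnames.index(w)]])
    return refs, names, (np.array(pos) if pos else np.empty((0, 3)))


def _hydrogens_near(model: AtomicModel, ref: ResidueRef,
                    donor_pos: np.ndarray) -> np.ndarray:
    sel = (model.chain.astype(str) == ref.chain) & (model.resnum == ref.resnum)
    hyd = sel & np.array([str(e).upper() == "H" for e in model.element])
    pos = model.xyz[hyd]
    if len(pos) == 0:
        return pos
    return pos[np.linalg.norm(pos - donor_pos, axis=1) < 1.3]


def find_polar_contacts(model_a: AtomicModel, model_b: AtomicModel,
                        params: ContactParams = ContactParams(),
                        ) -> list[PolarContact]:
    """Hydrogen bonds and salt bridges between two models in a common frame.

    Donor–acceptor pairs within the H-bond cutoff count as hydrogen bonds;
    when donor hydrogens are present the D–H...A angle must exceed the
    minimum, otherwise the screen runs distance-only (with a warning).
    Salt bridges are opposite-charge side-chain nitrogen/oxygen pairs
    within the salt-bridge cutoff; a pair reported as a salt bridge is not
    re-reported as a hydrogen bond. Contacts are symmetric: swapping the
    two models swaps donor/acceptor roles of the same contacts.
    """
    has_h = any(str(e).upper() == "H" for e in model_a.element) and \
        any(str(e).upper() == "H" for e in model_b.element)
    if not has_h:
        warnings.warn("models lack hydrogens; H-bond angle criterion skipped "
                      "(distance-only mode)")
    contacts: list[PolarContact] = []
    salt_pairs: set[tuple] = set()

    # salt bridges first
    for (pa, pb) in ((model_a, model_b), (model_b, model_a)):
        prefs, pnames, ppos = _polar_atoms(pa, _POSITIVE, None)
        nrefs, nnames, npos = _polar_atoms(pb, _NEGATIVE, None)
        if len(ppos) == 0 or len(npos) == 0:
            continue
        d = cdist(ppos, npos)
        for i, j in zip(*np.where(d <= params.salt_bridge_cutoff)):
            key = tuple(sorted([(prefs[i].chain, prefs[i].resnum, pnames[i]),
                                (nrefs[j].chain, nrefs[j].resnum, nnames[j])]))
            if key in salt_pairs:
                continue
            salt_pairs.add(key)
            contacts.append(PolarContact("salt-bridge", prefs[i], nrefs[j],
                                         pnames[i], nnames[j], float(d[i, j])))

    # hydrogen bonds, both directions (donor in A, acceptor in B and vice versa)
    for (da, ab) in ((model_a, model_b), (model_b, model_a)):
        drefs, dnames, dpos = _polar_atoms(da, _SC_DONORS, backbone="N")
        arefs, anames, apos = _polar_atoms(ab, _SC_ACCEPTORS, backbone="O")
        if len(dpos) == 0 or len(apos) == 0:
            continue
        d = cdist(dpos, apos)
        for i, j in zip(*np.where(d <= params.hbond_cutoff)):
            key = tuple(sorted([(drefs[i].chain, drefs[i].resnum, dnames[i]),
                                (arefs[j].chain, arefs[j].resnum, anames[j])]))
            if key in salt_pairs:
                continue
            if has_h:
                hpos = _hydrogens_near(da, drefs[i], dpos[i])
                if len(hpos):
                    v1 = dpos[i] - hpos  # H->D
                    v2 = apos[j] - hpos  # H->A
                    cosang = np.sum(v1 * v2, axis=1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
                    ang = np.rad2deg(np.arccos(np.clip(cosang, -1, 1)))
                    if ang.max() < params.hbond_angle_min:
                        continue
            contacts.append(PolarContact("hydrogen-bond", drefs[i], arefs[j],
                                         dnames[i], anames[j], float(d[i, j])))
    contacts.sort(key=lambda c: c.distance)
    return contacts
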