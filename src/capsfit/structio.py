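"""Structural data model and file I/O.

Defines the three containers the rest of the package works with —
:class:`AtomicModel`, :class:`DensityMap` and :class:`SequenceRecord` — and
readers/writers for PDB, mmCIF, MRC/CCP4-2014 and FASTA built on gemmi and
biopython conventions.

Conventions
-----------
* Coordinates are always in Å, maps are right-handed orthogonal grids.
* Per-residue model confidence (pLDDT for predicted models) lives in the
  B-factor column, the de-facto convention for predictions; the reader
  surfaces whatever the column holds and leaves semantics to the caller.
* Map origin follows the MRC2014 ORIGIN field, falling back to
  ``nstart * voxel`` when ORIGIN is all-zero (EMDB depositions vary).
* The PDB dialect is limited to <= 99,999 atoms and single-character chain
  ids; larger assemblies must use mmCIF.
"""

from __future__ import annotations

import dataclasses
import struct as _struct
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomicModel",
    "DensityMap",
    "SequenceRecord",
    "FormatError",
    "read_model",
    "write_model",
    "read_map",
    "write_map",
    "read_sequences",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

PDB_MAX_ATOMS = 99_999
PDB_MAX_RESSEQ = 9_999


class FormatError(ValueError):
    """Raised when a structure, map or sequence file cannot be parsed or written."""


@dataclasses.dataclass
class AtomicModel:
    """Flat atom-table representation of a (possibly multi-chain) model.

    All per-atom columns are parallel arrays of length ``n_atoms``.
    ``confidence`` holds the per-residue confidence (0-100) replicated on
    each atom of the residue; it is stored in / read from the B-factor
    column on disk.
    """

    chain: np.ndarray  # str
    resnum: np.ndarray  # int
    resname: np.ndarray  # str, 3-letter code
    atname: np.ndarray  # str
    element: np.ndarray  # str
    xyz: np.ndarray  # (n, 3) float, Å
    confidence: np.ndarray  # float, 0-100
    occupancy: np.ndarray  # float

    def __post_init__(self) -> None:
        n = len(self.chain)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=np.int64)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atname = np.asarray(self.atname, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        for arr in (self.resnum, self.resname, self.atname, self.element,
                    self.confidence, self.occupancy):
            if len(arr) != n:
                raise ValueError("atom table columns have unequal lengths")

    # -- basic queries ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def is_empty(self) -> bool:
        return self.n_atoms == 0

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if self.n_atoms and (self.confidence.min() < 0 or self.confidence.max() > 100):
            raise ValueError("confidence outside [0, 100]")
        if any(e == "" for e in self.element):
            raise ValueError("empty element symbol")
        for ch in np.unique(self.chain.astype(str)):
            sel = self.chain.astype(str) == ch
            # residue numbers must identify residues uniquely within a chain
            pairs = {}
            for rn, rname in zip(self.resnum[sel], self.resname[sel]):
                if pairs.setdefault(int(rn), rname) != rname:
                    raise ValueError(f"residue number {rn} reused within chain {ch}")

    def select(self, mask: np.ndarray) -> "AtomicModel":
        mask = np.asarray(mask, dtype=bool)
        return AtomicModel(self.chain[mask], self.resnum[mask], self.resname[mask],
                           self.atname[mask], self.element[mask], self.xyz[mask],
                           self.confidence[mask], self.occupancy[mask])

    def copy(self) -> "AtomicModel":
        return self.select(np.ones(self.n_atoms, dtype=bool))

    def residues(self) -> Iterator[tuple[str, int, np.ndarray]]:
        """Yield ``(chain, resnum, atom-index array)`` in first-appearance order."""
        order: dict[tuple[str, int], list[int]] = {}
        for i, (ch, rn) in enumerate(zip(self.chain, self.resnum)):
            order.setdefault((str(ch), int(rn)), []).append(i)
        for (ch, rn), idx in order.items():
            yield ch, rn, np.asarray(idx, dtype=int)

    @property
    def n_residues(self) -> int:
        return len({(str(c), int(r)) for c, r in zip(self.chain, self.resnum)})

    # -- geometry ---------------------------------------------------------
    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        out = self.copy()
        out.xyz = self.xyz @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return out

    def translated(self, shift: np.ndarray) -> "AtomicModel":
        return self.transformed(np.eye(3), shift)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([gemmi.Element(str(e)).atomic_number for e in self.element],
                        dtype=float)

    @staticmethod
    def concatenate(models: Sequence["AtomicModel"]) -> "AtomicModel":
        if not models:
            return empty_model()
        return AtomicModel(*[np.concatenate([getattr(m, f.name) for m in models])
                             for f in dataclasses.fields(AtomicModel)])


def empty_model() -> AtomicModel:
    z = np.empty(0, dtype=object)
    return AtomicModel(z.copy(), np.empty(0, int), z.copy(), z.copy(), z.copy(),
                       np.empty((0, 3)), np.empty(0), np.empty(0))


@dataclasses.dataclass
class DensityMap:
    """A 3-D scalar field on an orthogonal grid.

    ``grid`` is indexed ``[ix, iy, iz]``; ``origin`` is the world coordinate
    (Å) of the centre of voxel ``(0, 0, 0)``; ``voxel`` gives the Å spacing
    per axis. ``resolution`` is nominal metadata carried along from the
    reconstruction — it is never recomputed here.
    """

    grid: np.ndarray
    voxel: np.ndarray  # (3,) Å
    origin: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3-D with all dimensions >= 1")
        self.voxel = np.broadcast_to(np.asarray(self.voxel, float), (3,)).copy()
        if np.any(self.voxel <= 0):
            raise ValueError("voxel size must be positive on all axes")
        self.origin = np.asarray(self.origin, float).reshape(3).copy()
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel))

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel.copy(), self.origin.copy(),
                          self.resolution)

    # -- coordinate mapping ----------------------------------------------
    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world Å coordinates to (fractional) voxel indices."""
        return (np.asarray(points, float) - self.origin) / self.voxel

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, float) * self.voxel + self.origin

    def value_at(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolated density at world coordinates (trilinear by default)."""
        from scipy.ndimage import map_coordinates

        vox = np.atleast_2d(self.world_to_voxel(points))
        return map_coordinates(self.grid.astype(float), vox.T, order=order,
                               mode="constant", cval=0.0)

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres."""
        return tuple(self.origin[i] + self.voxel[i] * np.arange(self.grid.shape[i])
                     for i in range(3))  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: identifier plus canonical amino-acid letters (+X)."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.identifier!r}")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-amino-acid letters: "
                f"{sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Atomic model I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("pdb", "mmcif"):
            raise ValueError(f"unknown dialect {dialect!r}; use 'pdb' or 'mmcif'")
        return dialect
    suffix = Path(path).suffix.lower()
    return "mmcif" if suffix in (".cif", ".mmcif") else "pdb"


def read_model(path: str | Path, dialect: str | None = None) -> AtomicModel:
    """Read the first model block of a PDB or mmCIF file.

    The B-factor column is surfaced as per-residue ``confidence``. For
    alternate locations only the highest-occupancy conformer is kept.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = gemmi.CoorFormat.Pdb if _infer_dialect(path, dialect) == "pdb" \
        else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as "
                          f"{_infer_dialect(path, dialect)}: {exc}") from exc
    st.remove_alternative_conformations()  # keeps highest occupancy
    if len(st) == 0:
        raise FormatError(f"{path}: no model block found")
    model = st[0]
    rows: list[tuple] = []
    for chain in model:
        for res in chain:
            for atom in res:
                elem = atom.element.name or atom.name[:1]
                rows.append((chain.name, res.seqid.num, res.name, atom.name, elem,
                             (atom.pos.x, atom.pos.y, atom.pos.z),
                             atom.b_iso, atom.occ))
    if not rows:
        raise FormatError(f"{path}: model block contains no atoms")
    cols = list(zip(*rows))
    return AtomicModel(np.array(cols[0], object), np.array(cols[1], int),
                       np.array(cols[2], object), np.array(cols[3], object),
                       np.array(cols[4], object), np.array(cols[5], float),
                       np.array(cols[6], float), np.array(cols[7], float))


def _to_gemmi(model: AtomicModel, name: str = "capsfit") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    current: dict[str, gemmi.Chain] = {}
    res_cache: dict[tuple[str, int], gemmi.Residue] = {}
    for i in range(model.n_atoms):
        ch_id = str(model.chain[i])
        if ch_id not in current:
            current[ch_id] = gemmi.Chain(ch_id)
        key = (ch_id, int(model.resnum[i]))
        res = res_cache.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
            res.het_flag = "A"
            current[ch_id].add_residue(res)
            res = current[ch_id][-1]
            res_cache[key] = res
        at = gemmi.Atom()
        at.name = str(model.atname[i])
        at.element = gemmi.Element(str(model.element[i]))
        at.pos = gemmi.Position(*model.xyz[i])
        at.b_iso = float(model.confidence[i])
        at.occ = float(model.occupancy[i])
        res.add_atom(at)
    for chain in current.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path: str | Path,
                dialect: str | None = None) -> None:
    """Write a model as PDB or mmCIF (inferred from the extension by default).

    The fixed-width PDB dialect is refused for models that cannot be
    represented in it (too many atoms, >62 chains, multi-character chain
    ids, residue numbers above 9999); the error advises mmCIF.
    """
    if model.is_empty:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    d = _infer_dialect(path, dialect)
    if d == "pdb":
        chains = set(map(str, model.chain))
        problems = []
        if model.n_atoms > PDB_MAX_ATOMS:
            problems.append(f"{model.n_atoms} atoms > {PDB_MAX_ATOMS}")
        if len(chains) > 62:
            problems.append(f"{len(chains)} chains > 62 single-char ids")
        if any(len(c) > 1 for c in chains):
            problems.append("multi-character chain ids")
        if model.n_atoms and int(model.resnum.max()) > PDB_MAX_RESSEQ:
            problems.append(f"residue number {int(model.resnum.max())} "
                            f"> {PDB_MAX_RESSEQ}")
        if problems:
            raise FormatError("model does not fit the fixed-width PDB format ("
                              + "; ".join(problems) + "); write mmCIF instead")
    st = _to_gemmi(model)
    path.parent.mkdir(parents=True, exist_ok=True)
    if d == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Density map I/O (MRC / CCP4 2014)
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4-2014 map, normalising on-disk axis order to X,Y,Z.

    The ORIGIN header is honoured; when it is all-zero the origin falls back
    to ``nstart * voxel``. Non-orthogonal cells are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as MRC/CCP4: {exc}") from exc
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise FormatError(f"{path}: non-orthogonal cell "
                          f"({cell.alpha}, {cell.beta}, {cell.gamma}) unsupported")
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True)
    if not np.all(np.isfinite(grid)):
        raise FormatError(f"{path}: map contains non-finite values")
    nx, ny, nz = grid.shape
    # sampling counts (MX, MY, MZ) define the voxel size
    mx = m.header_i32(8) or nx
    my = m.header_i32(9) or ny
    mz = m.header_i32(10) or nz
    voxel = np.array([cell.a / mx, cell.b / my, cell.c / mz])
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    if np.all(origin == 0):
        nstart = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)], float)
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map as MRC/CCP4-2014 (mode 2, X fastest), preserving values bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    g.spacegroup = gemmi.SpaceGroup("P1")
    nx, ny, nz = dmap.grid.shape
    g.set_unit_cell(gemmi.UnitCell(dmap.voxel[0] * nx, dmap.voxel[1] * ny,
                                   dmap.voxel[2] * nz, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file ('>' headers, wrapped lines) into SequenceRecords."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    ident: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ident is not None:
                    records.append(SequenceRecord(ident, "".join(chunks)))
                ident = line[1:].split()[0] if len(line) > 1 else ""
                if not ident:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if ident is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                chunks.append(line.upper())
    if ident is not None:
        records.append(SequenceRecord(ident, "".join(chunks)))
    return records
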