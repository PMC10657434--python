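"""Candidate-model pools for the multi-round screening protocol.

Each screening round docks a pool of rigid candidates into the unassigned
sub-maps. Pools are built from predicted full-length models by (a) removing
low-confidence residues (per-residue confidence, pLDDT convention, strictly
below 70 by default), then (b) fragmenting: whole models in round ``full``,
N/C half-models in round ``halves``, and sliding sequence windows in the
fragment rounds (150-residue windows with 125-residue overlap, and
75-residue windows with 60-residue overlap for the fine verification pool).

Fragments are cut from the existing predicted coordinates rather than
re-predicted; they inherit the parent's coordinates and confidences.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structio import AtomicModel, SequenceRecord

__all__ = [
    "FragmentScheme",
    "Candidate",
    "CandidatePool",
    "WIN150",
    "WIN75",
    "trim_by_confidence",
    "split_halves",
    "window_fragments",
    "build_pool",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 70.0


@dataclasses.dataclass(frozen=True)
class FragmentScheme:
    """Sliding-window fragmentation: ``window`` residues advancing by
    ``window - overlap``."""

    window: int
    overlap: int

    def __post_init__(self) -> None:
        if not (0 < self.overlap < self.window):
            raise ValueError(f"need 0 < overlap < window, got "
                             f"overlap={self.overlap}, window={self.window}")

    @property
    def step(self) -> int:
        return self.window - self.overlap


#: Coarse localisation fragments: 150-residue windows, 125-residue overlap.
WIN150 = FragmentScheme(window=150, overlap=125)
#: Fine verification fragments: 75-residue windows, 60-residue overlap.
WIN75 = FragmentScheme(window=75, overlap=60)

_ROUND_SCHEMES = {"win150": WIN150, "win75": WIN75}


@dataclasses.dataclass
class Candidate:
    """One pool member: a trimmed model or fragment with its provenance."""

    model: AtomicModel
    source_id: str
    round: int
    residue_range: tuple[int, int]  # inclusive, in source numbering
    trim_report: list[int] = dataclasses.field(default_factory=list)
    candidate_id: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"bad residue range {self.residue_range}")
        if not self.candidate_id:
            self.candidate_id = f"{self.source_id}:{lo}-{hi}"
        if not self.model.is_empty:
            rn = self.model.resnum
            if rn.min() < lo or rn.max() > hi:
                raise ValueError(
                    f"candidate {self.candidate_id}: model residues "
                    f"[{rn.min()}, {rn.max()}] escape range {self.residue_range}")

    @property
    def n_residues(self) -> int:
        return self.model.n_residues


@dataclasses.dataclass
class CandidatePool:
    candidates: list[Candidate]
    round_label: str = ""

    def __post_init__(self) -> None:
        ids = [c.candidate_id for c in self.candidates]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate candidate ids in pool: {dup}")

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def sources(self) -> list[str]:
        return sorted({c.source_id for c in self.candidates})

    def manifest(self) -> pd.DataFrame:
        rows = [{"candidate_id": c.candidate_id, "source": c.source_id,
                 "round": c.round, "first": c.residue_range[0],
                 "last": c.residue_range[1], "residues_kept": c.n_residues,
                 "residues_removed": len(c.trim_report)}
                for c in self.candidates]
        return pd.DataFrame(rows)

    def write_manifest(self, path: str | Path) -> None:
        self.manifest().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def trim_by_confidence(model: AtomicModel,
                       threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                       ) -> tuple[AtomicModel, list[int]]:
    """Remove residues whose confidence is strictly below ``threshold``.

    Residues exactly at the threshold are kept. Chain and residue numbering
    of the survivors is unchanged. Returns ``(trimmed model, removed
    residue numbers)``; an empty result is legal.
    """
    keep = np.ones(model.n_atoms, dtype=bool)
    removed: list[int] = []
    for ch, rn, idx in model.residues():
        conf = float(model.confidence[idx].max())
        if conf < threshold:
            keep[idx] = False
            removed.append(rn)
    return model.select(keep), removed


def split_halves(candidate: Candidate) -> tuple[Candidate, Candidate]:
    """Split a candidate at the midpoint of its residue range.

    The N-half receives the extra residue when the range length is odd.
    Coordinates are copied, not re-predicted.
    """
    lo, hi = candidate.residue_range
    if hi - lo + 1 < 2:
        raise ValueError(f"cannot split single-residue candidate "
                         f"{candidate.candidate_id}")
    mid = lo + (hi - lo + 1 + 1) // 2 - 1  # last residue of the N-half
    halves = []
    for (a, b), tag in (((lo, mid), "N"), ((mid + 1, hi), "C")):
        in_range = (candidate.model.resnum >= a) & (candidate.model.resnum <= b)
        halves.append(Candidate(
            model=candidate.model.select(in_range),
            source_id=candidate.source_id,
            round=candidate.round + 1,
            residue_range=(a, b),
            trim_report=[r for r in candidate.trim_report if a <= r <= b],
            candidate_id=f"{candidate.source_id}:{a}-{b}:{tag}half",
        ))
    return halves[0], halves[1]


def window_fragments(sequence_length: int,
                     scheme: FragmentScheme) -> list[tuple[int, int]]:
    """Residue ranges (1-based, inclusive) of sliding windows over a sequence.

    Regular windows start at 1, 1+step, 1+2*step, ... while a full window
    fits; if the last regular window stops short of the C-terminus one extra
    window anchored at the C-terminus is appended so the union of windows
    always covers [1, L]. Sequences shorter than the window yield a single
    whole-sequence window.
    """
    if sequence_length < 1:
        raise ValueError("sequence length must be >= 1")
    L, w = sequence_length, scheme.window
    if L <= w:
        return [(1, L)]
    ranges = [(s, s + w - 1) for s in range(1, L - w + 2, scheme.step)]
    if ranges[-1][1] < L:
        ranges.append((L - w + 1, L))
    return ranges


def _fragment_candidate(cand: Candidate, scheme: FragmentScheme) -> list[Candidate]:
    lo, hi = cand.residue_range
    out = []
    for a0, b0 in window_fragments(hi - lo + 1, scheme):
        a, b = lo + a0 - 1, lo + b0 - 1
        in_win = (cand.model.resnum >= a) & (cand.model.resnum <= b)
        out.append(Candidate(
            model=cand.model.select(in_win),
            source_id=cand.source_id,
            round=cand.round + 1,
            residue_range=(a, b),
            trim_report=[r for r in cand.trim_report if a <= r <= b],
        ))
    return out


def _as_full_candidate(src: Candidate | SequenceRecord | AtomicModel,
                       source_id: str | None = None) -> Candidate:
    if isinstance(src, Candidate):
        return src
    if isinstance(src, SequenceRecord):
        raise TypeError(
            f"source {src.identifier!r} is a bare sequence; pool building needs "
            "predicted coordinates (fragments are cut from existing models)")
    model = src
    if model.is_empty:
        raise ValueError("empty source model")
    return Candidate(model=model.copy(), source_id=source_id or "model",
                     round=0,
                     residue_range=(int(model.resnum.min()), int(model.resnum.max())))


def build_pool(sources: Sequence[Candidate | AtomicModel],
               round: str = "full",
               scheme: FragmentScheme | None = None,
               confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
               source_ids: Sequence[str] | None = None) -> CandidatePool:
    """Build the candidate pool for one screening round.

    ``round`` is one of ``full`` (whole trimmed models), ``halves`` (N/C
    half-models), ``win150``/``win75`` (sliding windows), or ``custom`` with
    an explicit ``scheme``. Fragmentation is applied first, then
    per-residue confidence trimming; candidates left empty by trimming are
    dropped with a logged reason.
    """
    if not sources:
        raise ValueError("no sources given")
    if round == "custom":
        if scheme is None:
            raise ValueError("round 'custom' needs an explicit FragmentScheme")
    elif round in _ROUND_SCHEMES:
        scheme = _ROUND_SCHEMES[round]
    elif round not in ("full", "halves"):
        raise ValueError(f"unknown round {round!r}")

    base = [_as_full_candidate(s, source_ids[i] if source_ids else f"model{i}")
            for i, s in enumerate(sources)]
    expanded: list[Candidate] = []
    for cand in base:
        if round == "full":
            expanded.append(cand)
        elif round == "halves":
            expanded.extend(split_halves(cand))
        else:
            expanded.extend(_fragment_candidate(cand, scheme))  # type: ignore[arg-type]

    kept: list[Candidate] = []
    for cand in expanded:
        trimmed, removed = trim_by_confidence(cand.model, confidence_threshold)
        if trimmed.is_empty:
            logger.info("dropping %s: all %d residues below confidence %.1f",
                        cand.candidate_id, len(removed), confidence_threshold)
            continue
        kept.append(dataclasses.replace(
            cand, model=trimmed,
            trim_report=sorted(set(cand.trim_report) | set(removed))))
    return CandidatePool(kept, round_label=round)
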