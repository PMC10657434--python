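"""Multi-round assignment: pool -> dock -> accept -> subtract -> repeat.

The screening protocol starts from whole trimmed predicted models, docks
every pool member into every unassigned sub-map, accepts the clear
winners, removes their density, and retries the leftovers with
progressively finer candidates (half-models, then 150-residue windows,
then 75-residue windows for verification). The manual accept step of the
original workflow is replaced here by an explicit three-parameter rule —
minimum CC, minimum CC gap to the best competitor of a different source,
and minimum model-in-density coverage — so runs are reproducible and the
evidence for every decision lands in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dock import (DockParams, FitResult, cc_score, exhaustive_dock,
                   model_coverage, refine_pose)
from .pool import Candidate, CandidatePool, FragmentScheme, build_pool
from .rigid import Pose
from .structio import AtomicModel, DensityMap
from .voldens import SubMap, segment_map, subtract_fitted

__all__ = [
    "RoundSpec",
    "SegmentationParams",
    "AssignmentReport",
    "VerificationRecord",
    "default_schedule",
    "dock_pool_into_submap",
    "run_round",
    "run_pipeline",
    "verify_assignment",
]

logger = logging.getLogger(__name__)

#: Docking knobs used by the pipeline rounds: a coarse deterministic
#: rotation grid whose winners are polished off-grid afterwards.
PIPELINE_DOCK_PARAMS = DockParams(angular_step=45.0, top_n=8, refine=False,
                                  lowpass_template=True)


@dataclasses.dataclass(frozen=True)
class RoundSpec:
    """One screening round: which pool to build and how to accept fits."""

    pool_round: str = "full"
    dock_params: DockParams = PIPELINE_DOCK_PARAMS
    min_cc: float = 0.6
    min_gap: float = 0.05
    min_coverage: float = 0.6
    refine_top: int = 4  # candidates whose best pose gets local polishing
    scheme: FragmentScheme | None = None  # for pool_round == 'custom'

    def __post_init__(self) -> None:
        if not (0 < self.min_cc <= 1):
            raise ValueError("min CC must lie in (0, 1]")
        if self.min_gap < 0:
            raise ValueError("CC gap must be >= 0")
        if not (0 <= self.min_coverage <= 1):
            raise ValueError("coverage must lie in [0, 1]")


def default_schedule() -> list[RoundSpec]:
    """Whole models, then halves, then 150-residue and 75-residue windows."""
    return [RoundSpec(pool_round=r) for r in ("full", "halves", "win150", "win75")]


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """How the map is split into sub-maps before round one.

    ``threshold`` is an absolute density level; when None it defaults to
    ``auto_fraction`` of the map maximum. ``min_volume`` (Å^3) drops
    speckle components.
    """

    threshold: float | None = None
    auto_fraction: float = 0.25
    min_volume: float = 800.0
    method: str = "connected"

    def resolve_threshold(self, dmap: DensityMap) -> float:
        if self.threshold is not None:
            return self.threshold
        return float(self.auto_fraction * dmap.grid.max())


@dataclasses.dataclass
class VerificationRecord:
    submap_label: str
    accepted_source: str
    confirmed: bool
    margin: float  # CC margin of the source's best fine fragment
    infinite_margin: bool  # no competitor fragments existed
    best_fragment: str


@dataclasses.dataclass
class AssignmentReport:
    """Auditable outcome of a pipeline run."""

    accepted: list[dict]  # submap, candidate, source, cc, coverage, round, pose
    unassigned: list[str]
    residual_fraction: dict[str, float]
    n_submaps: int
    rounds_run: list[str]
    config: dict
    log: pd.DataFrame  # every scored fit

    def accepted_sources(self) -> dict[str, str]:
        """submap label -> accepted source id."""
        return {a["submap"]: a["source"] for a in self.accepted}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_submaps": self.n_submaps,
            "rounds_run": self.rounds_run,
            "accepted": [
                {k: (round(v, 6) if isinstance(v, float) else v)
                 for k, v in a.items()} for a in self.accepted],
            "unassigned": self.unassigned,
            "residual_fraction": {k: round(v, 6)
                                  for k, v in self.residual_fraction.items()},
            "config": self.config,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Docking a pool into one sub-map
# ---------------------------------------------------------------------------

def dock_pool_into_submap(pool: CandidatePool, submap: SubMap,
                          params: DockParams = PIPELINE_DOCK_PARAMS,
                          refine_top: int = 4) -> list[FitResult]:
    """Best fit of every pool candidate in one sub-map, ranked by CC.

    Every candidate is docked exhaustively, keeping its distinct top poses;
    each plausible basin (within 0.18 CC of the candidate's best) gets a
    short local refinement, and the candidate's score is its best refined
    pose. The ``refine_top`` leading candidates then receive a full polish.
    The final list holds one fit per candidate, ranked by CC (ties:
    smaller translation norm, then candidate id).
    """
    search = dataclasses.replace(params, refine=False)
    # quick in-basin refinement scores with the unfiltered template (cheaper,
    # same optimum neighbourhood); final polish uses the full scoring model
    quick_params = dataclasses.replace(params, lowpass_template=False)
    by_id = {c.candidate_id: c for c in pool}
    best: list[FitResult] = []
    for cand in pool:
        fits = exhaustive_dock(cand, submap, search)
        # short in-basin refinement of the plausible basins: the coarse
        # rotation grid rarely lands inside the correct basin, and the
        # correct basin is often not the best-scoring coarse pose
        plausible = [f for f in fits if f.cc >= fits[0].cc - 0.18]
        quick: list[tuple[float, Pose]] = [(f.cc, f.pose) for f in fits]
        for f in plausible:
            pose, _ = refine_pose(submap, cand.model, f.pose, quick_params,
                                  max_iter=30)
            quick.append((cc_score(submap, cand.model, pose, params), pose))
        cc, pose = max(quick, key=lambda q: q[0])
        top = fits[0]
        top.cc, top.pose = cc, pose
        best.append(top)
    best.sort(key=lambda f: (-f.cc, float(np.linalg.norm(f.pose.translation)),
                             f.candidate_id))
    for f in best[:refine_top]:
        pose, cc = refine_pose(submap, by_id[f.candidate_id].model, f.pose,
                               params, max_iter=120)
        if cc > f.cc:
            f.cc, f.pose = cc, pose
    best.sort(key=lambda f: (-f.cc, float(np.linalg.norm(f.pose.translation)),
                             f.candidate_id))
    for rank, f in enumerate(best, start=1):
        f.rank = rank
    return best


def _excess_sum(grid: np.ndarray, mask: np.ndarray, level: float) -> float:
    """Density above the segmentation level inside the mask (noise-robust)."""
    return float(np.clip(grid[mask] - level, 0.0, None).sum())


@dataclasses.dataclass
class RoundResult:
    accepted: list[FitResult]
    remaining: list[SubMap]
    residual_fraction: dict[str, float]
    log_rows: list[dict]


def run_round(pool: CandidatePool, submaps: Sequence[SubMap], spec: RoundSpec,
              retain_threshold: float = 0.25,
              mask_radius: float = 3.0, soft_edge: float = 3.0) -> RoundResult:
    """Dock a pool into every sub-map, accept winners, subtract their density.

    For each sub-map the best fit is accepted iff its CC clears ``min_cc``,
    beats the best fit of any *different* source by ``min_gap``, and covers
    the sub-map's density with at least ``min_coverage`` of its atoms.
    Accepted density is masked out; sub-maps whose residual (positive)
    density exceeds ``retain_threshold`` of the original — and all sub-maps
    without an acceptance — continue to the next round. Zero acceptances is
    a legal outcome.
    """
    if len(pool) == 0 or not submaps:
        raise ValueError("round needs a non-empty pool and at least one sub-map")
    by_id = {c.candidate_id: c for c in pool}
    accepted: list[FitResult] = []
    remaining: list[SubMap] = []
    residual: dict[str, float] = {}
    log_rows: list[dict] = []
    for sm in submaps:
        fits = dock_pool_into_submap(pool, sm, spec.dock_params,
                                     spec.refine_top)
        for f in fits:
            log_rows.append({"round": spec.pool_round, "submap": sm.label,
                             "candidate": f.candidate_id, "source": f.source_id,
                             "rank": f.rank, "cc": f.cc})
        best = fits[0]
        # the ambiguity (gap) rule only counts *viable* competitors: a rival
        # of a different source close in CC but itself failing the coverage
        # rule could never be accepted, so it does not block the winner
        blocking = []
        for f in fits:
            if f.source_id == best.source_id or f.cc <= best.cc - spec.min_gap:
                continue
            f_cov = model_coverage(sm, by_id[f.candidate_id].model, f.pose)
            if f_cov >= spec.min_coverage:
                blocking.append(f.cc)
        gap_ok = not blocking
        cand = by_id[best.candidate_id]
        coverage = model_coverage(sm, cand.model, best.pose)
        ok = best.cc >= spec.min_cc and gap_ok and coverage >= spec.min_coverage
        logger.info("submap %s: best %s cc=%.3f coverage=%.2f -> %s",
                    sm.label, best.candidate_id, best.cc, coverage,
                    "accept" if ok else "reject")
        if not ok:
            remaining.append(sm)
            residual[sm.label] = 1.0
            continue
        accepted.append(best)
        before = _excess_sum(sm.parent.grid, sm.mask, sm.level)
        residual_map = subtract_fitted(sm.parent, [(cand.model, best.pose)],
                                       mask_radius=mask_radius,
                                       soft_edge=soft_edge)
        after = _excess_sum(residual_map.grid, sm.mask, sm.level)
        frac = after / before if before > 0 else 0.0
        residual[sm.label] = frac
        if frac > retain_threshold:
            remaining.append(sm.with_parent_grid(residual_map.grid))
    return RoundResult(accepted, remaining, residual, log_rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(sources: dict[str, AtomicModel], dmap: DensityMap,
                 schedule: Sequence[RoundSpec] | None = None,
                 segmentation: SegmentationParams = SegmentationParams(),
                 retain_threshold: float = 0.25,
                 crop_margin: float = 8.0) -> AssignmentReport:
    """Segment a map and run the screening rounds in order.

    ``sources`` maps source ids to full predicted models (with per-residue
    confidence). Pools are rebuilt from the sources for every round
    (full, halves, windows, ...); sub-maps assigned in earlier rounds drop
    out, the rest carry their subtracted density forward. Deterministic
    given inputs and parameters; always returns a report.
    """
    if schedule is None:
        schedule = default_schedule()
    if not schedule:
        raise ValueError("empty schedule")
    ids = list(sources)
    models = [sources[i] for i in ids]
    config = {
        "segmentation": {"threshold": segmentation.threshold,
                         "auto_fraction": segmentation.auto_fraction,
                         "min_volume": segmentation.min_volume,
                         "method": segmentation.method},
        "retain_threshold": retain_threshold,
        "rounds": [{"pool": s.pool_round, "min_cc": s.min_cc,
                    "min_gap": s.min_gap, "min_coverage": s.min_coverage,
                    "angular_step": s.dock_params.angular_step}
                   for s in schedule],
    }
    submaps = segment_map(dmap, segmentation.resolve_threshold(dmap),
                          min_volume=segmentation.min_volume,
                          method=segmentation.method)
    submaps = [sm.cropped(crop_margin) for sm in submaps]
    n_submaps = len(submaps)
    all_labels = [sm.label for sm in submaps]
    accepted: list[dict] = []
    residual: dict[str, float] = {lbl: 1.0 for lbl in all_labels}
    log_rows: list[dict] = []
    rounds_run: list[str] = []
    remaining = submaps
    for spec in schedule:
        if not remaining:
            break
        pool = build_pool(models, round=spec.pool_round, scheme=spec.scheme,
                          source_ids=ids)
        if len(pool) == 0:
            logger.warning("round %s: empty pool after trimming; skipped",
                           spec.pool_round)
            continue
        rounds_run.append(spec.pool_round)
        rr = run_round(pool, remaining, spec, retain_threshold=retain_threshold)
        for f in rr.accepted:
            accepted.append({"submap": f.submap_label, "candidate": f.candidate_id,
                             "source": f.source_id, "cc": float(f.cc),
                             "round": spec.pool_round,
                             "pose": [float(v) for v in f.pose.as_flat()]})
        residual.update(rr.residual_fraction)
        log_rows.extend(rr.log_rows)
        remaining = rr.remaining
    assigned_labels = {a["submap"] for a in accepted}
    return AssignmentReport(
        accepted=accepted,
        unassigned=[lbl for lbl in all_labels if lbl not in assigned_labels],
        residual_fraction=residual,
        n_submaps=n_submaps,
        rounds_run=rounds_run,
        config=config,
        log=pd.DataFrame(log_rows),
    )


# ---------------------------------------------------------------------------
# Fine-fragment verification
# ---------------------------------------------------------------------------

def verify_assignment(sources: dict[str, AtomicModel], submap: SubMap,
                      accepted_source: str,
                      scheme: FragmentScheme | None = None,
                      params: DockParams = PIPELINE_DOCK_PARAMS,
                      refine_top: int = 2) -> VerificationRecord:
    """Check an acceptance with a fine-fragment pool (75/60 by default).

    All sources are refragmented; the assignment is confirmed iff the best
    fine fragment in the region belongs to the accepted source. The margin
    is the CC lead over the best competitor fragment; with no competitors
    the margin is +inf and flagged.
    """
    ids = list(sources)
    pool = build_pool([sources[i] for i in ids],
                      round="custom" if scheme else "win75", scheme=scheme,
                      source_ids=ids)
    fits = dock_pool_into_submap(pool, submap, params, refine_top=refine_top)
    best = fits[0]
    same = [f.cc for f in fits if f.source_id == accepted_source]
    others = [f.cc for f in fits if f.source_id != accepted_source]
    if not same:
        return VerificationRecord(submap.label, accepted_source, False,
                                  float("-inf"), False, best.candidate_id)
    infinite = not others
    margin = float("inf") if infinite else max(same) - max(others)
    confirmed = best.source_id == accepted_source
    return VerificationRecord(submap.label, accepted_source, confirmed,
                              margin, infinite, best.candidate_id)
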