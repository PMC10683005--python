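"""Taxonomically informed filtering of the major candidate annotations.

After the peak-shape stage, several shape-correlated features may still
compete under one CAD peak.  Two further filters narrow the "major"
metabolome:

* taxonomic prioritization — if any candidate under the peak was already
  reported in the studied species (taxonomic distance score 0.9) keep
  exactly those; else if any at the genus level (0.8) keep exactly those;
  below genus no prioritization is applied and all pass through;
* confidence filter — keep only candidates whose composite annotation
  score is strictly above the confidence threshold (default 0.4); a score
  above 1 survives but is flagged as suspect.

Demoted features are never dropped: they remain in the output classified
as "minor".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .models import CandidateAnnotation, FeaturePeakLink

__all__ = [
    "FilterConfig",
    "StageCounts",
    "STAGES",
    "best_candidates",
    "taxonomic_prioritization",
    "confidence_filter",
    "apply_filter_cascade",
]

STAGES = ("none", "shape", "shape+taxon", "shape+taxon+confidence")

OVER_UNITY_FLAG = "final_score>1"


@dataclass(frozen=True)
class FilterConfig:
    species_score: float = 0.9
    genus_score: float = 0.8
    min_confidence: float = 0.4
    score_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.species_score <= self.genus_score:
            raise ValueError("species_score must exceed genus_score")


@dataclass
class StageCounts:
    """Per-stage bookkeeping for Table-1-style statistics and alluvial plots."""

    stage: str
    features_linked: int
    structures_per_peak: dict[int, int] = field(default_factory=dict)
    surviving_ids: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


def best_candidates(annotations: list[CandidateAnnotation]) -> dict[int, CandidateAnnotation]:
    """Best-ranked candidate per feature (rank 1, or lowest rank present)."""
    best: dict[int, CandidateAnnotation] = {}
    for a in annotations:
        cur = best.get(a.feature_id)
        if cur is None or a.rank < cur.rank:
            best[a.feature_id] = a
    return best


def _matches(score: float, target: float, tol: float) -> bool:
    return abs(score - target) <= tol


def taxonomic_prioritization(
        majors_under_peak: list[tuple[FeaturePeakLink, Optional[CandidateAnnotation]]],
        config: FilterConfig = FilterConfig()) -> list[FeaturePeakLink]:
    """Retain the taxonomically closest candidates under one CAD peak.

    Species-level candidates (score 0.9 within tolerance) win over
    genus-level (0.8); when several sit at the winning level all are kept
    (no rationale to choose one over another).  With no species- or
    genus-level candidate everything passes through to the confidence
    stage.  Returns the retained links; callers demote the rest.
    """
    def level(ann: Optional[CandidateAnnotation]) -> int:
        if ann is None:
            return 0
        if _matches(ann.taxonomic_distance_score, config.species_score, config.score_tolerance):
            return 2
        if _matches(ann.taxonomic_distance_score, config.genus_score, config.score_tolerance):
            return 1
        return 0

    levels = [level(ann) for _, ann in majors_under_peak]
    top = max(levels, default=0)
    if top == 0:
        return [lk for lk, _ in majors_under_peak]
    return [lk for lk, lv in zip((lk for lk, _ in majors_under_peak), levels) if lv == top]


def confidence_filter(
        candidates: list[tuple[FeaturePeakLink, Optional[CandidateAnnotation]]],
        config: FilterConfig = FilterConfig()) -> tuple[list[FeaturePeakLink], set[int]]:
    """Keep links whose candidate's final score is strictly above threshold.

    Returns (retained links, feature ids flagged for an over-unity score).
    An unannotated link can never be confident.
    """
    retained: list[FeaturePeakLink] = []
    flagged: set[int] = set()
    for lk, ann in candidates:
        if ann is None or not ann.final_score > config.min_confidence:
            continue
        if ann.final_score > 1.0:
            flagged.add(lk.feature_id)
        retained.append(lk)
    return retained, flagged


def apply_filter_cascade(links: list[FeaturePeakLink],
                         annotations: list[CandidateAnnotation],
                         config: FilterConfig = FilterConfig(),
                         ) -> tuple[list[FeaturePeakLink], list[StageCounts], set[int]]:
    """Run shape -> taxonomic -> confidence and set ``status_final``.

    Every input feature appears exactly once in the output; demoted
    features stay as "minor" links.  Returns the final links, one
    :class:`StageCounts` per stage (structure counts per peak use the
    best-ranked candidate's structure id), and the over-unity-flagged
    feature ids.
    """
    known = {lk.feature_id for lk in links}
    for a in annotations:
        if a.feature_id not in known:
            raise ValueError(f"annotation references unknown feature {a.feature_id}")
    best = best_candidates(annotations)

    def stage_counts(stage: str, surviving: set[int]) -> StageCounts:
        per_peak: dict[int, set[str]] = {}
        n_linked = 0
        for lk in links:
            if lk.peak_id is None or lk.feature_id not in surviving:
                continue
            n_linked += 1
            ann = best.get(lk.feature_id)
            if ann is not None:
                per_peak.setdefault(lk.peak_id, set()).add(ann.structure_id)
            else:
                per_peak.setdefault(lk.peak_id, set())
        linked_surviving = {lk.feature_id for lk in links
                            if lk.peak_id is not None and lk.feature_id in surviving}
        return StageCounts(stage, n_linked,
                           {p: len(s) for p, s in per_peak.items()},
                           linked_surviving)

    all_linked = {lk.feature_id for lk in links if lk.peak_id is not None}
    shape_majors = {lk.feature_id for lk in links if lk.status_shape == "major"}

    # taxonomic prioritization, per peak
    by_peak: dict[int, list[FeaturePeakLink]] = {}
    for lk in links:
        if lk.feature_id in shape_majors and lk.peak_id is not None:
            by_peak.setdefault(lk.peak_id, []).append(lk)
    taxon_survivors: set[int] = set()
    for pid, plinks in by_peak.items():
        pairs = [(lk, best.get(lk.feature_id)) for lk in plinks]
        for lk in taxonomic_prioritization(pairs, config):
            taxon_survivors.add(lk.feature_id)

    conf_pairs = [(lk, best.get(lk.feature_id))
                  for lk in links if lk.feature_id in taxon_survivors]
    conf_links, flagged = confidence_filter(conf_pairs, config)
    final_majors = {lk.feature_id for lk in conf_links}

    out: list[FeaturePeakLink] = []
    for lk in links:
        status = "major" if lk.feature_id in final_majors else "minor"
        out.append(replace(lk, status_final=status))

    counts = [
        stage_counts("none", all_linked),
        stage_counts("shape", shape_majors),
        stage_counts("shape+taxon", taxon_survivors),
        stage_counts("shape+taxon+confidence", final_majors),
    ]
    return out, counts, flagged
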