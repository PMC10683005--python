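"""Summary statistics, per-peak reports and visualization-ready structures.

Everything here consumes the classified links and filtered annotations;
no re-integration or re-scoring happens at this layer, so bar values and
area fractions are exactly the integrated CAD peak areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import networkx as nx

from .filtering import STAGES, StageCounts, best_candidates
from .models import CadPeak, CandidateAnnotation, FeaturePeakLink

__all__ = [
    "SummaryStats",
    "ReportRow",
    "BarSeries",
    "summarize",
    "build_report",
    "pseudochromatogram",
    "treemap",
    "decorate_network",
    "alluvial_counts",
    "ALLUVIAL_BINS",
]

log = logging.getLogger(__name__)


def _round1(x: float) -> float:
    """Round half-up to one decimal (the precision of the printed tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStats:
    """Table-1-style statistics at one filter stage.

    Means are taken over peaks retaining at least one linked feature at
    that stage; with no linked features they are ``None``.
    """

    stage: str
    picked_features: int
    picked_peaks: int
    features_linked: int
    mean_features_per_peak: Optional[float]
    mean_structures_per_peak: Optional[float]
    mean_mfs_per_peak: Optional[float]
    mean_classes_per_peak: Optional[float]


@dataclass
class ReportRow:
    """One row of the automated major-metabolome report."""

    peak_id: int
    apex_rt: float
    area: float
    area_fraction: float
    candidates: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class BarSeries:
    """Pseudochromatogram bars: integrated areas along retention time."""

    bars: list[tuple[float, float, str]]  # (rt, value, category)
    category_scheme: str
    value_scheme: str = "cad_area"


def _surviving(links: list[FeaturePeakLink], stage: str) -> list[FeaturePeakLink]:
    if stage == "none":
        return [lk for lk in links if lk.peak_id is not None]
    if stage == "shape":
        return [lk for lk in links if lk.status_shape == "major"]
    if stage in ("shape+taxon", "shape+taxon+confidence"):
        return [lk for lk in links if lk.status_final == "major"]
    raise ValueError(f"unknown stage {stage!r}")


def summarize(links: list[FeaturePeakLink],
              annotations: list[CandidateAnnotation],
              stage: str,
              picked_features: Optional[int] = None,
              picked_peaks: Optional[int] = None,
              surviving_ids: Optional[set[int]] = None) -> SummaryStats:
    """Per-stage feature/peak statistics.

    ``features_linked`` counts peak-linked features surviving the stage;
    the means divide by the number of peaks with at least one surviving
    link.  Structures, molecular formulas and chemical classes count
    distinct values among the surviving features' best-ranked candidates
    per peak.  Means are rounded half-up to one decimal.

    ``surviving_ids`` can pin the surviving feature set explicitly (for
    intermediate cascade stages whose survivors are not recoverable from
    the final link statuses alone); otherwise it is derived from the link
    statuses: "none" keeps every peak-linked feature, "shape" the
    shape-stage majors, the later stages the final majors.
    """
    if surviving_ids is not None:
        surv = [lk for lk in links
                if lk.peak_id is not None and lk.feature_id in surviving_ids]
    else:
        surv = _surviving(links, stage)
    best = best_candidates(annotations)
    per_peak: dict[int, list[Optional[CandidateAnnotation]]] = {}
    for lk in surv:
        per_peak.setdefault(lk.peak_id, []).append(best.get(lk.feature_id))
    n_peaks_contributing = len(per_peak)
    n_linked = len(surv)
    if n_peaks_contributing == 0:
        means = (None, None, None, None)
    else:
        def mean_distinct(attr: str) -> float:
            total = 0
            for anns in per_peak.values():
                total += len({getattr(a, attr) for a in anns if a is not None})
            return _round1(total / n_peaks_contributing)

        means = (
            _round1(n_linked / n_peaks_contributing),
            mean_distinct("structure_id"),
            mean_distinct("molecular_formula"),
            mean_distinct("npc_class"),
        )
    return SummaryStats(
        stage=stage,
        picked_features=picked_features if picked_features is not None else len(links),
        picked_peaks=picked_peaks if picked_peaks is not None else n_peaks_contributing,
        features_linked=n_linked,
        mean_features_per_peak=means[0],
        mean_structures_per_peak=means[1],
        mean_mfs_per_peak=means[2],
        mean_classes_per_peak=means[3],
    )


def _retained_by_peak(links: list[FeaturePeakLink]) -> dict[int, list[FeaturePeakLink]]:
    out: dict[int, list[FeaturePeakLink]] = {}
    for lk in links:
        if lk.status_final == "major" and lk.peak_id is not None:
            out.setdefault(lk.peak_id, []).append(lk)
    return out


def build_report(peaks: list[CadPeak], links: list[FeaturePeakLink],
                 annotations: list[CandidateAnnotation],
                 flagged: Optional[set[int]] = None) -> list[ReportRow]:
    """One report row per integrated CAD peak, after the full cascade.

    Peaks retaining at least one final-major feature carry their retained
    candidates; peaks with none are still listed (empty candidate list,
    flagged ``unannotated``) since they should be prioritized for manual
    investigation.  ``area_fraction`` is each peak's share of the total
    integrated area over all peaks.
    """
    flagged = flagged or set()
    best = best_candidates(annotations)
    by_peak = _retained_by_peak(links)
    total_area = sum(p.area for p in peaks)
    rows: list[ReportRow] = []
    for p in sorted(peaks, key=lambda p: p.apex_time):
        cands, row_flags = [], []
        for lk in by_peak.get(p.peak_id, []):
            ann = best.get(lk.feature_id)
            if ann is None:
                continue
            cands.append({
                "feature_id": lk.feature_id,
                "structure_id": ann.structure_id,
                "molecular_formula": ann.molecular_formula,
                "npc_pathway": ann.npc_pathway,
                "npc_superclass": ann.npc_superclass,
                "npc_class": ann.npc_class,
                "taxon_level": ann.taxon_level,
                "closest_organism": ann.closest_organism,
                "final_score": ann.final_score,
            })
            if lk.feature_id in flagged:
                row_flags.append(f"{OVER_UNITY_PREFIX}{lk.feature_id}")
        if not cands:
            row_flags.append("unannotated")
        rows.append(ReportRow(
            peak_id=p.peak_id, apex_rt=p.apex_time, area=p.area,
            area_fraction=(p.area / total_area) if total_area > 0 else 0.0,
            candidates=cands, flags=row_flags))
    return rows


OVER_UNITY_PREFIX = "final_score>1:feature_"

BAR_SCHEMES = ("taxon-level", "npc-pathway", "npc-superclass")


def pseudochromatogram(peaks: list[CadPeak], links: list[FeaturePeakLink],
                       annotations: list[CandidateAnnotation],
                       scheme: str = "taxon-level") -> BarSeries:
    """One bar per peak at its apex with the integrated area as value.

    The category is the retained candidate's taxon level (or NPClassifier
    pathway/superclass depending on ``scheme``); peaks without a retained
    annotation get category ``"none"``.
    """
    if scheme not in BAR_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {BAR_SCHEMES}")
    attr = {"taxon-level": "taxon_level", "npc-pathway": "npc_pathway",
            "npc-superclass": "npc_superclass"}[scheme]
    best = best_candidates(annotations)
    by_peak = _retained_by_peak(links)
    bars = []
    for p in sorted(peaks, key=lambda p: p.apex_time):
        anns = [best.get(lk.feature_id) for lk in by_peak.get(p.peak_id, [])]
        anns = [a for a in anns if a is not None]
        category = getattr(anns[0], attr) if anns else "none"
        bars.append((p.apex_time, p.area, category))
    return BarSeries(bars=bars, category_scheme=scheme)


def treemap(links: list[FeaturePeakLink],
            annotations: list[CandidateAnnotation],
            peaks: list[CadPeak],
            weight: str = "cad_area") -> dict[str, float]:
    """Fractional composition per NPClassifier pathway.

    ``weight="cad_area"``: CAD area share per pathway over the final
    majors; a peak with several retained candidates splits its area
    equally among them.  ``weight="count"``: share of minor-feature
    annotation counts per pathway, ignoring MS intensity.  Fractions sum
    to 1 for nonempty input.
    """
    best = best_candidates(annotations)
    totals: dict[str, float] = {}
    if weight == "cad_area":
        area_by_peak = {p.peak_id: p.area for p in peaks}
        by_peak = _retained_by_peak(links)
        for pid, plinks in by_peak.items():
            anns = [best.get(lk.feature_id) for lk in plinks]
            anns = [a for a in anns if a is not None]
            if not anns:
                continue
            share = area_by_peak.get(pid, 0.0) / len(anns)
            for a in anns:
                totals[a.npc_pathway] = totals.get(a.npc_pathway, 0.0) + share
    elif weight == "count":
        for lk in links:
            if lk.status_final != "minor":
                continue
            a = best.get(lk.feature_id)
            if a is None:
                continue
            totals[a.npc_pathway] = totals.get(a.npc_pathway, 0.0) + 1.0
    else:
        raise ValueError(f"unknown weight {weight!r}")
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {k: v / grand for k, v in sorted(totals.items())}


def decorate_network(network: nx.Graph, peaks: list[CadPeak],
                     links: list[FeaturePeakLink],
                     annotations: Optional[list[CandidateAnnotation]] = None) -> nx.Graph:
    """Attach CAD semiquantitation to a molecular network's nodes.

    Each node (keyed by feature id) gains ``cad_area`` (area of its linked
    peak, 0 for minors and unlinked features), ``status_final`` and
    ``npc_pathway`` of its retained candidate (``"unannotated"`` when
    absent).  Edges are untouched.
    """
    best = best_candidates(annotations or [])
    area_by_peak = {p.peak_id: p.area for p in peaks}
    link_by_feature = {lk.feature_id: lk for lk in links}
    g = network.copy()
    for node in g.nodes:
        lk = link_by_feature.get(int(node))
        if lk is None:
            log.warning("node %r has no link record; decorating with defaults", node)
            g.nodes[node].update(cad_area=0.0, status_final="minor",
                                 npc_pathway="unannotated")
            continue
        major = lk.status_final == "major"
        area = area_by_peak.get(lk.peak_id, 0.0) if (major and lk.peak_id is not None) else 0.0
        ann = best.get(lk.feature_id) if major else None
        g.nodes[node].update(
            cad_area=float(area),
            status_final=lk.status_final,
            npc_pathway=ann.npc_pathway if ann is not None else "unannotated")
    return g


ALLUVIAL_BINS = ("0", "1", "2", "3-5", ">5")


def _bin_label(n: int) -> str:
    if n <= 2:
        return str(n)
    return "3-5" if n <= 5 else ">5"


def alluvial_counts(stage_counts: list[StageCounts]) -> list[tuple[str, str, int]]:
    """Bin peaks by distinct-candidate-structure count at each stage.

    Returns (stage, bin label, number of peaks) triples; at every stage
    the bins partition the peaks that were linked at the unfiltered stage,
    so peaks losing all candidates migrate into the "0" bin.
    """
    if not stage_counts:
        return []
    all_peaks: set[int] = set()
    for sc in stage_counts:
        all_peaks.update(sc.structures_per_peak)
    out: list[tuple[str, str, int]] = []
    for sc in stage_counts:
        bins = {b: 0 for b in ALLUVIAL_BINS}
        for pid in all_peaks:
            bins[_bin_label(sc.structures_per_peak.get(pid, 0))] += 1
        for b in ALLUVIAL_BINS:
            out.append((sc.stage, b, bins[b]))
    return out
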