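"""End-to-end orchestration: pretreat -> detect -> link -> filter -> report.

This is the programmatic equivalent of running the CLI stages in order,
returning every intermediate the tests and reports need.  All outputs are
deterministic functions of the inputs and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .filtering import FilterConfig, StageCounts, apply_filter_cascade
from .io_formats import write_network, write_peak_report
from .linking import LinkConfig, classify_major_minor
from .models import (CadPeak, CandidateAnnotation, ChromatogramSet,
                     FeaturePeakLink, MsFeature, Trace)
from .peaks import DEFAULT_MIN_SNR, DEFAULT_MIN_WIDTH, detect_peaks, estimate_noise
from .pretreatment import PretreatmentConfig, pretreat
from .reporting import (ReportRow, SummaryStats, alluvial_counts, build_report,
                        pseudochromatogram, summarize, treemap)

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineResult:
    cad_pretreated: Trace
    peaks: list[CadPeak]
    links: list[FeaturePeakLink]
    stage_counts: list[StageCounts]
    flagged: set[int]
    summaries: list[SummaryStats]
    report: list[ReportRow]
    network: Optional[nx.Graph] = None


def run_pipeline(chromatograms: ChromatogramSet,
                 features: list[MsFeature],
                 annotations: list[CandidateAnnotation],
                 pre_config: PretreatmentConfig = PretreatmentConfig(),
                 link_config: LinkConfig = LinkConfig(),
                 filter_config: FilterConfig = FilterConfig(),
                 min_snr: float = DEFAULT_MIN_SNR,
                 min_width: float = DEFAULT_MIN_WIDTH,
                 network: Optional[nx.Graph] = None) -> PipelineResult:
    """Run the whole composition-assessment workflow on one LC run."""
    raw_cad = chromatograms.cad()
    raw_noise = estimate_noise(raw_cad).level if len(raw_cad) >= 10 else None
    cad = pretreat(raw_cad, pre_config.lag_cad_to_ms, pre_config)
    peaks = detect_peaks(cad, min_snr=min_snr, min_width=min_width,
                         noise_level=raw_noise)
    # shape comparison uses the unsharpened (denoised) CAD signal
    cad_link = pretreat(raw_cad, pre_config.lag_cad_to_ms, pre_config,
                        sharpen=False)
    links = classify_major_minor(features, peaks, cad_link, link_config)
    links, counts, flagged = apply_filter_cascade(links, annotations, filter_config)
    summaries = [summarize(links, annotations, sc.stage,
                           surviving_ids=sc.surviving_ids)
                 for sc in counts]
    report = build_report(peaks, links, annotations, flagged)
    decorated = None
    if network is not None:
        from .reporting import decorate_network
        decorated = decorate_network(network, peaks, links, annotations)
    return PipelineResult(cad, peaks, links, counts, flagged, summaries,
                          report, decorated)


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  annotations: Optional[list[CandidateAnnotation]] = None) -> dict[str, Path]:
    """Write the deterministic TSV/JSON artifact set for one run."""
    annotations = annotations or []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    peak_lines = ["peak_id\tapex_rt\tleft\tright\theight\tarea"]
    for p in result.peaks:
        peak_lines.append(f"{p.peak_id}\t{p.apex_time:.10g}\t{p.left_bound:.10g}"
                          f"\t{p.right_bound:.10g}\t{p.height:.10g}\t{p.area:.10g}")
    paths["peaks"] = out / "peaks.tsv"
    paths["peaks"].write_text("\n".join(peak_lines) + "\n")

    link_lines = ["feature_id\tpeak_id\tsimilarity\tstatus_shape\tstatus_final"]
    for lk in result.links:
        pid = "" if lk.peak_id is None else str(lk.peak_id)
        sim = "" if lk.similarity is None else f"{lk.similarity:.10g}"
        link_lines.append(f"{lk.feature_id}\t{pid}\t{sim}\t{lk.status_shape}"
                          f"\t{lk.status_final}")
    paths["links"] = out / "links.tsv"
    paths["links"].write_text("\n".join(link_lines) + "\n")

    stage_lines = ["stage\tfeatures_linked"]
    for sc in result.stage_counts:
        stage_lines.append(f"{sc.stage}\t{sc.features_linked}")
    paths["stages"] = out / "stage_counts.tsv"
    paths["stages"].write_text("\n".join(stage_lines) + "\n")

    paths["report"] = write_peak_report(result.report, out / "report.tsv")

    viz = {
        "pseudochromatogram_taxon": [
            list(b) for b in pseudochromatogram(result.peaks, result.links,
                                                annotations, "taxon-level").bars],
        "treemap_major_area": treemap(result.links, annotations, result.peaks,
                                      "cad_area"),
        "treemap_minor_count": treemap(result.links, annotations, result.peaks,
                                       "count"),
        "alluvial": [list(t) for t in alluvial_counts(result.stage_counts)],
    }
    paths["viz"] = out / "visualization.json"
    paths["viz"].write_text(json.dumps(viz, indent=1, sort_keys=True))

    if result.network is not None:
        paths["network"] = write_network(result.network, out / "network_decorated.graphml")
    return paths
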