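"""Attribution of MS features to CAD peaks by peak-shape similarity.

A feature is a candidate of the unique CAD peak whose minima-to-minima
interval contains the feature's retention-time apex.  For each candidate
pair the CAD segment and the feature XIC segment are cropped to the peak
bounds, normalized in both retention time (affine to [0, 1]) and intensity
(min-max per segment), resampled to a common grid, and compared by Pearson
correlation with closest-point pairing.  Features reaching the similarity
threshold (default 0.8) are "major"; everything else — including every
feature outside any CAD peak — is "minor".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CadPeak, FeaturePeakLink, MsFeature, Trace

__all__ = [
    "LinkConfig",
    "assign_candidates",
    "normalize_pair",
    "shape_similarity",
    "classify_major_minor",
]


@dataclass(frozen=True)
class LinkConfig:
    similarity_threshold: float = 0.8
    resample_rate: float = 2.0  # Hz, shared CAD/MS comparison grid

    def __post_init__(self) -> None:
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be > 0")


def assign_candidates(features: list[MsFeature],
                      peaks: list[CadPeak]) -> dict[int, list[int]]:
    """Map each peak id to the feature ids whose rt apex it contains.

    Features and peaks must share the (aligned) MS time axis.  A feature
    whose apex lies exactly on a boundary shared by two peaks goes to the
    earlier peak; features outside all peaks are absent from the map.
    """
    ordered = sorted(peaks, key=lambda p: p.apex_time)
    out: dict[int, list[int]] = {p.peak_id: [] for p in ordered}
    for f in sorted(features, key=lambda f: (f.rt_apex, f.feature_id)):
        for p in ordered:
            if p.contains(f.rt_apex):
                out[p.peak_id].append(f.feature_id)
                break
    return out


def _minmax(y: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi - lo == 0.0:
        return np.zeros_like(y)  # constant segment carries no shape information
    return (y - lo) / (hi - lo)


def normalize_pair(cad_segment: Trace, xic_segment: Trace, peak: CadPeak,
                   rate: float = 2.0) -> tuple[Trace, Trace]:
    """Crop both traces to the peak bounds and normalize for comparison.

    Retention time is mapped affinely onto [0, 1] between the peak's two
    minima, intensity is min-max scaled to [0, 1] per segment (a constant
    segment maps to all zeros), and both segments are resampled onto the
    same uniform grid.  The grid density follows ``rate`` applied to the
    peak's duration, with at least 3 points.
    """
    lo, hi = peak.left_bound, peak.right_bound
    for seg, name in ((cad_segment, "CAD"), (xic_segment, "XIC")):
        if seg.times[-1] <= lo or seg.times[0] >= hi:
            raise ValueError(f"{name} segment has empty overlap with peak bounds [{lo}, {hi}]")
    n = max(3, int(round((hi - lo) * 60.0 * rate)) + 1)
    grid = np.linspace(0.0, 1.0, n)
    out = []
    for seg in (cad_segment, xic_segment):
        u = (seg.times - lo) / (hi - lo)
        vals = np.interp(grid, u, _minmax(seg.intensities))
        vals = _minmax(vals) if np.ptp(vals) > 0 else np.zeros_like(vals)
        out.append(Trace(detector_id=seg.detector_id, times=grid, intensities=vals,
                         sampling_rate_hint=rate))
    return out[0], out[1]


def shape_similarity(a: Trace, b: Trace) -> float:
    """Pearson correlation of two normalized segments, closest-point paired.

    Each point of the shorter trace is paired with the temporally closest
    point of the longer one (ties break to the earlier point).  Returns 0
    when either paired vector has zero variance.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 points per segment")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    # closest-point pairing with ties to the earlier point
    idx = np.searchsorted(long_.times, short.times)
    idx = np.clip(idx, 1, len(long_) - 1)
    left_dist = short.times - long_.times[idx - 1]
    right_dist = long_.times[idx] - short.times
    idx = np.where(left_dist <= right_dist, idx - 1, idx)
    u = short.intensities
    v = long_.intensities[idx]
    if u.size < 3:
        raise ValueError("fewer than 3 pairable points")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return 0.0
    r = np.corrcoef(u, v)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def classify_major_minor(features: list[MsFeature], peaks: list[CadPeak],
                         cad_trace: Trace,
                         config: LinkConfig = LinkConfig()) -> list[FeaturePeakLink]:
    """Link every feature to at most one CAD peak and classify it.

    Candidates (apex-contained features) get a peak-shape similarity
    against the CAD segment of their peak; ``status_shape`` is "major" iff
    the similarity reaches the threshold.  Non-candidates are minor with no
    peak.  Every feature appears in exactly one link; ``status_final`` is
    initialized to ``status_shape`` and refined by the annotation filter
    cascade.
    """
    peak_by_id = {p.peak_id: p for p in peaks}
    cand = assign_candidates(features, peaks)
    parent: dict[int, int] = {}
    for pid, fids in cand.items():
        for fid in fids:
            parent[fid] = pid
    links: list[FeaturePeakLink] = []
    for f in sorted(features, key=lambda f: f.feature_id):
        pid = parent.get(f.feature_id)
        if pid is None:
            links.append(FeaturePeakLink(f.feature_id, None, None, "minor"))
            continue
        peak = peak_by_id[pid]
        try:
            cad_seg = cad_trace.crop(peak.left_bound, peak.right_bound)
            xic_seg = f.xic.crop(max(peak.left_bound, f.xic.span[0]),
                                 min(peak.right_bound, f.xic.span[1]))
            cad_n, xic_n = normalize_pair(cad_seg, xic_seg, peak, config.resample_rate)
            sim = shape_similarity(cad_n, xic_n)
        except ValueError:
            # XIC does not usably cover the peak: no shape evidence
            sim = 0.0
        status = "major" if sim >= config.similarity_threshold else "minor"
        links.append(FeaturePeakLink(f.feature_id, pid, sim, status, status))
    return links
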