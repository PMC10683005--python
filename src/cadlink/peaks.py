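"""Peak detection and integration on the pretreated one-dimensional CAD trace.

The CAD signal has no spectral dimension, so peaks are picked with simple
one-dimensional rules: local maxima gated by a robust noise estimate,
bounded by the nearest local minima, and integrated trapezoidally above a
per-peak linear baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .models import CadPeak, Trace

__all__ = ["NoiseEstimate", "estimate_noise", "detect_peaks", "integrate_peak"]

log = logging.getLogger(__name__)

DEFAULT_MIN_SNR = 5.0
DEFAULT_MIN_WIDTH = 0.05  # minutes


@dataclass(frozen=True)
class NoiseEstimate:
    level: float   # CAD units
    method: str

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def estimate_noise(trace: Trace) -> NoiseEstimate:
    """Robust local noise level of a trace.

    Uses the median absolute deviation of the first difference: for i.i.d.
    noise of standard deviation sigma riding on a slowly varying signal,
    ``diff`` has standard deviation ``sigma * sqrt(2)``, so
    ``1.4826 * MAD(diff) / sqrt(2)`` estimates sigma while ignoring peaks.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 points to estimate noise")
    d = np.diff(trace.intensities)
    mad = np.median(np.abs(d - np.median(d)))
    return NoiseEstimate(level=float(1.4826 * mad / np.sqrt(2.0)), method="mad-diff")


def _local_minima_indices(y: np.ndarray) -> np.ndarray:
    """Indices of local minima plus both endpoints, sorted."""
    minima, _ = find_peaks(-y)
    return np.unique(np.concatenate(([0], minima, [y.size - 1])))


def detect_peaks(trace: Trace, min_snr: float = DEFAULT_MIN_SNR,
                 min_width: float = DEFAULT_MIN_WIDTH,
                 noise_level: Optional[float] = None) -> list[CadPeak]:
    """Detect and integrate peaks on a pretreated, uniformly sampled trace.

    Apexes are local maxima whose baseline-corrected height is at least
    ``min_snr`` times the robust noise level; bounds run to the nearest
    local minimum on each side (or the trace ends).  Peaks narrower than
    ``min_width`` minutes are discarded.  On a plateau the leftmost sample
    is the apex.  Returns peaks sorted by apex time with sequential ids.

    ``noise_level`` should be the noise of the *raw* signal (the
    first-difference estimator underestimates on an already low-passed
    trace); when omitted it is estimated from ``trace`` itself.
    """
    if not trace.is_uniform():
        raise ValueError("detect_peaks requires a uniformly sampled trace")
    y = trace.intensities
    t = trace.times
    if noise_level is not None:
        noise = float(noise_level)
    else:
        try:
            noise = estimate_noise(trace).level
        except ValueError:
            noise = 0.0
    apexes, props = find_peaks(y, plateau_size=1)
    # leftmost sample of a flat apex is the apex
    apexes = props.get("left_edges", apexes)
    if apexes.size == 0:
        return []
    minima = _local_minima_indices(y)
    out: list[CadPeak] = []
    for ap in apexes:
        li = minima[minima < ap]
        ri = minima[minima > ap]
        if li.size == 0 or ri.size == 0:
            continue
        lo, hi = int(li[-1]), int(ri[0])
        width = t[hi] - t[lo]
        if width < min_width:
            continue
        # height above the linear baseline through the two bound samples
        frac = (t[ap] - t[lo]) / (t[hi] - t[lo])
        baseline_at_apex = y[lo] + frac * (y[hi] - y[lo])
        height = float(y[ap] - baseline_at_apex)
        if height <= 0 or height < min_snr * noise:
            continue
        out.append(CadPeak(
            peak_id=0, apex_time=float(t[ap]), left_bound=float(t[lo]),
            right_bound=float(t[hi]), height=height, area=0.0))
    out.sort(key=lambda p: p.apex_time)
    peaks: list[CadPeak] = []
    for i, p in enumerate(out, start=1):
        area = _integrate(trace, p.left_bound, p.right_bound)
        peaks.append(CadPeak(peak_id=i, apex_time=p.apex_time, left_bound=p.left_bound,
                             right_bound=p.right_bound, height=p.height, area=area))
    return peaks


def _integrate(trace: Trace, left: float, right: float) -> float:
    t, y = trace.times, trace.intensities
    lo = int(np.searchsorted(t, left - 1e-12))
    hi = int(np.searchsorted(t, right + 1e-12)) - 1
    tt, yy = t[lo:hi + 1], y[lo:hi + 1]
    baseline = np.interp(tt, [tt[0], tt[-1]], [yy[0], yy[-1]])
    area = float(np.trapezoid(yy - baseline, tt))
    if area < 0:
        log.warning("negative baseline-subtracted area (%.3g) clamped to 0", area)
        area = 0.0
    return area


def integrate_peak(trace: Trace, peak: CadPeak) -> float:
    """Baseline-subtracted trapezoidal area of ``peak`` on ``trace``.

    The baseline is the straight line through the intensities at the two
    bounds; a negative net area is clamped to 0 with a warning.
    """
    t0, t1 = trace.span
    if peak.left_bound < t0 - 1e-9 or peak.right_bound > t1 + 1e-9:
        raise ValueError("peak bounds outside the trace span")
    return _integrate(trace, peak.left_bound, peak.right_bound)
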