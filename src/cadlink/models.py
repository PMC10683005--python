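"""Domain containers shared across the pipeline.

Times are always minutes internally; unit conversion happens once at the
mzML boundary.  Intensities keep each detector's native arbitrary units
(CAD: pA-equivalent, PDA: absorbance, MS: ion counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical detector labels.
DETECTORS = ("CAD", "PDA", "BPI_pos", "BPI_neg", "XIC")


@dataclass(frozen=True)
class Trace:
    """One detector's intensity-versus-time series.

    Parameters
    ----------
    detector_id :
        One of :data:`DETECTORS`.
    times :
        Strictly increasing retention times in minutes.
    intensities :
        Finite detector readings, same length as ``times`` (length >= 2).
    sampling_rate_hint :
        Acquisition frequency in Hz when known, else ``None``.
    """

    detector_id: str
    times: np.ndarray
    intensities: np.ndarray
    sampling_rate_hint: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("trace values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True if the sampling interval is constant to relative tolerance."""
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-12))

    @property
    def step(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.times)))

    def with_values(self, *, times=None, intensities=None, detector_id=None,
                    sampling_rate_hint=None) -> "Trace":
        return Trace(
            detector_id=detector_id if detector_id is not None else self.detector_id,
            times=self.times if times is None else np.asarray(times, float),
            intensities=self.intensities if intensities is None else np.asarray(intensities, float),
            sampling_rate_hint=self.sampling_rate_hint if sampling_rate_hint is None else sampling_rate_hint,
        )

    def crop(self, t_lo: float, t_hi: float) -> "Trace":
        """Sub-trace of samples with t_lo <= t <= t_hi (inclusive)."""
        m = (self.times >= t_lo) & (self.times <= t_hi)
        if m.sum() < 2:
            raise ValueError(f"crop [{t_lo}, {t_hi}] leaves fewer than 2 samples")
        return self.with_values(times=self.times[m], intensities=self.intensities[m])


@dataclass
class ChromatogramSet:
    """Traces of one LC run keyed by detector id (at most one per detector)."""

    traces: dict[str, Trace]
    source_path: str = ""
    ionization_mode: str = "both"  # pos | neg | both

    def __post_init__(self) -> None:
        for key, tr in self.traces.items():
            if key != tr.detector_id:
                raise ValueError(f"key {key!r} != trace detector_id {tr.detector_id!r}")

    @property
    def has_cad(self) -> bool:
        return "CAD" in self.traces

    def cad(self) -> Trace:
        if not self.has_cad:
            raise KeyError("no CAD trace in this chromatogram set")
        return self.traces["CAD"]


@dataclass(frozen=True)
class MsFeature:
    """An untargeted MS feature with its extracted ion chromatogram (XIC)."""

    feature_id: int
    mode: str           # pos | neg
    mz: float           # Da
    rt_apex: float      # minutes
    height: float       # counts
    xic: Trace

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be > 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")
        lo, hi = self.xic.span
        if not (lo <= self.rt_apex <= hi):
            raise ValueError(
                f"feature {self.feature_id}: rt_apex {self.rt_apex} outside XIC span [{lo}, {hi}]")


#: taxon levels ordered from closest to farthest.
TAXON_LEVELS = ("species", "genus", "family", "order", "class", "none")


@dataclass(frozen=True)
class CandidateAnnotation:
    """One ranked structure hypothesis for a feature.

    ``taxonomic_distance_score`` rewards structures already reported in
    organisms close to the studied species (0.9 same species, 0.8 same
    genus).  ``final_score`` is the composite annotation confidence; values
    above 1 are permitted (and flagged downstream as suspect overfitting).
    """

    feature_id: int
    rank: int
    structure_id: str
    molecular_formula: str
    npc_pathway: str
    npc_superclass: str
    npc_class: str
    taxonomic_distance_score: float
    final_score: float
    closest_organism: str
    taxon_level: str = "none"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not np.isfinite(self.taxonomic_distance_score) or self.taxonomic_distance_score < 0:
            raise ValueError("taxonomic_distance_score must be finite and >= 0")
        if not np.isfinite(self.final_score) or self.final_score < 0:
            raise ValueError("final_score must be finite and >= 0")
        if self.taxon_level not in TAXON_LEVELS:
            raise ValueError(f"unknown taxon_level {self.taxon_level!r}")


@dataclass(frozen=True)
class CadPeak:
    """An integrated CAD peak bounded by its neighbouring minima."""

    peak_id: int
    apex_time: float    # minutes
    left_bound: float   # minutes
    right_bound: float  # minutes
    height: float       # CAD units above local baseline
    area: float         # CAD units * min, baseline-subtracted trapezoid

    def __post_init__(self) -> None:
        if not (self.left_bound < self.apex_time < self.right_bound):
            raise ValueError("need left_bound < apex_time < right_bound")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def contains(self, t: float) -> bool:
        return self.left_bound <= t <= self.right_bound


@dataclass
class FeaturePeakLink:
    """Attribution of one MS feature to (at most) one CAD peak.

    ``status_shape`` is the classification after the peak-shape stage;
    ``status_final`` after the full taxonomic + confidence cascade.
    """

    feature_id: int
    peak_id: Optional[int]
    similarity: Optional[float]
    status_shape: str          # major | minor
    status_final: str = "minor"

    def __post_init__(self) -> None:
        if self.peak_id is None and (self.similarity is not None or self.status_shape == "major"):
            raise ValueError("unlinked feature must have similarity None and be minor")
        for s in (self.status_shape, self.status_final):
            if s not in ("major", "minor"):
                raise ValueError(f"bad status {s!r}")
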