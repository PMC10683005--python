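"""Seeded, ground-truthed synthetic multi-detector datasets.

The generator emulates the data structure the pipeline assumes for a
natural-extract LC run with CAD, PDA and MS detection:

* a CAD trace sampled at 60 Hz (about 30x the MS1 rate) built as a sum of
  chromatographic peak shapes plus slow baseline drift and white noise,
  emitted on the CAD's own time axis (shifted relative to the MS axis by
  the instrument lag so the alignment step is exercised);
* per-peak MS feature XICs at 2 Hz: "majors" share the parent peak's
  shape up to a multiplicative scale and small noise, "decoys" are either
  retention-shifted copies or smooth shape-independent signals;
* ranked candidate annotation tables with controllable taxonomic-distance
  and confidence score distributions, by default planting exactly one
  species-level confident candidate per peak;
* a toy molecular network connecting features under the same peak.

Every draw comes from one seeded generator, so a given spec is
bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy.stats import exponnorm

from .io_formats import (write_annotation_table, write_feature_table,
                         write_fixture_mzml, write_network)
from .models import (CandidateAnnotation, ChromatogramSet, MsFeature, Trace)

__all__ = ["FixtureSpec", "GroundTruth", "FixtureBundle", "generate", "write_fixture"]

CAD_RATE = 60.0   # Hz; ~30x the MS1 rate, exercising the resampling path
MS_RATE = 2.0     # Hz

_PATHWAYS = [
    ("Terpenoids", "Triterpenoids", "Oleanane triterpenoids"),
    ("Terpenoids", "Iridoids", "Secoiridoid glycosides"),
    ("Shikimates and Phenylpropanoids", "Xanthones", "Simple xanthones"),
    ("Polyketides", "Xanthones", "Prenylated xanthones"),
    ("Alkaloids", "Monoterpene alkaloids", "Gentianine-type alkaloids"),
    ("Fatty acids", "Fatty acids and conjugates", "Unsaturated fatty acids"),
]
_ORGANISMS = {
    "species": "Swertia chirayita",
    "genus": "Swertia japonica",
    "family": "Gentiana lutea",
    "order": "Coffea arabica",
    "class": "Arabidopsis thaliana",
}
_TAX_TO_LEVEL = {0.9: "species", 0.8: "genus", 0.6: "family", 0.3: "order"}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; defaults are the package's reference study
    conditions (20 well-separated peaks, ~5 features each, 2% major noise,
    decoys shifted by at least 2 FWHM)."""

    n_peaks: int = 20
    rt_span: tuple[float, float] = (0.0, 20.0)     # minutes
    peak_shape: str = "gaussian"                   # gaussian | emg
    sigma_range: tuple[float, float] = (0.03, 0.07)    # minutes
    apex_height_range: tuple[float, float] = (50.0, 500.0)  # CAD units
    n_majors_per_peak: tuple[int, int] = (2, 3)
    n_decoys_per_peak: tuple[int, int] = (2, 3)
    major_noise_sd_frac: float = 0.02
    decoy_shift_min_fwhm: float = 2.0
    baseline_drift: float = 2.0                    # CAD units
    noise_sd: float = 1.0                          # CAD units
    emg_tau: float = 0.03                          # minutes, EMG tail constant
    lag_cad_to_ms: float = 0.055                   # minutes
    lag_pda_to_ms: float = 0.090                   # minutes
    species_fraction: float = 1.0    # fraction of peaks given exactly one
    #                                  species-level confident candidate
    tax_score_distribution: dict[float, float] = field(
        default_factory=lambda: {0.8: 0.15, 0.6: 0.35, 0.3: 0.5})
    confidence_distribution: tuple[float, float] = (0.05, 0.9)   # uniform bounds
    confident_range: tuple[float, float] = (0.5, 0.95)  # designated candidates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.peak_shape not in ("gaussian", "emg"):
            raise ValueError("peak_shape must be 'gaussian' or 'emg'")
        if not math.isclose(sum(self.tax_score_distribution.values()), 1.0, abs_tol=1e-9):
            raise ValueError("tax_score_distribution must sum to 1")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks."""

    peaks: list[dict]                 # apex, sigma, height, area (min/CAD units)
    features: dict[int, dict]         # fid -> kind, parent_peak, is_shape_major,
    #                                   is_final_major, tax score, confidence


@dataclass
class FixtureBundle:
    chromatograms: ChromatogramSet
    features: list[MsFeature]
    annotations: list[CandidateAnnotation]
    network: nx.Graph
    truth: GroundTruth


def _shape(times: np.ndarray, apex: float, sigma: float, height: float,
           kind: str, tau: float) -> np.ndarray:
    if kind == "gaussian":
        return height * np.exp(-0.5 * ((times - apex) / sigma) ** 2)
    k = tau / sigma
    pdf = exponnorm.pdf(times, K=k, loc=apex, scale=sigma)
    peak = pdf.max()
    return height * pdf / peak if peak > 0 else np.zeros_like(times)


def _plant_apexes(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.rt_span
    sig_max = spec.sigma_range[1]
    margin = 8.0 * sig_max
    usable = (hi - lo) - 2 * margin
    if spec.n_peaks == 0:
        return np.empty(0)
    if spec.n_peaks > 1:
        spacing = usable / (spec.n_peaks - 1)
        if spacing < 8.0 * sig_max:
            raise ValueError(
                f"rt_span too short for {spec.n_peaks} peaks at >=4 sigma spacing")
        amp = min(0.15 * spacing, 2.0 * sig_max)
        jitter = rng.uniform(-amp, amp, spec.n_peaks)
        apexes = lo + margin + spacing * np.arange(spec.n_peaks) + jitter
        return np.clip(apexes, lo + margin, hi - margin)
    if usable < 0:
        raise ValueError("rt_span too short for one peak")
    return np.array([lo + margin + rng.uniform(0, max(usable, 1e-9))])


def _smooth_random_shape(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shape-independent smooth decoy signal: a few random sinusoids."""
    u = (times - times[0]) / max(times[-1] - times[0], 1e-12)
    y = np.zeros_like(u)
    for _ in range(4):
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        y += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * freq * u + phase)
    y -= y.min()
    return y + 0.05 * abs(y).max()


def _ms_grid(lo: float, hi: float, span: tuple[float, float]) -> np.ndarray:
    lo = max(lo, span[0])
    hi = min(hi, span[1])
    dt = 1.0 / (60.0 * MS_RATE)
    n = int(math.floor((hi - lo) / dt)) + 1
    return lo + dt * np.arange(n)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build one seeded dataset bundle.

    The CAD (and PDA) traces are emitted on their own detector time axes,
    earlier than the MS axis by the configured lags; all feature XICs and
    ground truth live on the MS axis.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rt_span
    apexes = _plant_apexes(spec, rng)
    sigmas = rng.uniform(*spec.sigma_range, size=spec.n_peaks)
    heights = rng.uniform(*spec.apex_height_range, size=spec.n_peaks)

    # ---- CAD trace at 60 Hz on the MS axis, then shifted to the CAD axis
    n_cad = int(math.floor((hi - lo) * 60.0 * CAD_RATE)) + 1
    t_cad = lo + np.arange(n_cad) / (60.0 * CAD_RATE)
    clean = np.zeros_like(t_cad)
    for a, s, h in zip(apexes, sigmas, heights):
        clean += _shape(t_cad, a, s, h, spec.peak_shape, spec.emg_tau)
    drift = spec.baseline_drift * 0.5 * (1 + np.sin(2 * np.pi * (t_cad - lo) / max(hi - lo, 1e-9)))
    cad_y = clean + drift + rng.normal(0.0, spec.noise_sd, n_cad)
    cad = Trace("CAD", t_cad - spec.lag_cad_to_ms, cad_y, sampling_rate_hint=CAD_RATE)
    pda_y = 0.4 * clean + 0.2 * drift + rng.normal(0.0, 0.5 * spec.noise_sd, n_cad)
    pda = Trace("PDA", t_cad - spec.lag_pda_to_ms, pda_y, sampling_rate_hint=CAD_RATE)

    # ---- features
    features: list[MsFeature] = []
    truth_features: dict[int, dict] = {}
    designated: dict[int, Optional[int]] = {}
    fid = 0
    tax_vals = np.array(list(spec.tax_score_distribution))
    tax_probs = np.array([spec.tax_score_distribution[v] for v in tax_vals])
    for pi, (a, s, h) in enumerate(zip(apexes, sigmas, heights)):
        fwhm = 2.3548 * s
        majors = rng.integers(spec.n_majors_per_peak[0], spec.n_majors_per_peak[1] + 1)
        decoys = rng.integers(spec.n_decoys_per_peak[0], spec.n_decoys_per_peak[1] + 1)
        peak_fids: list[int] = []
        for _ in range(majors):
            fid += 1
            grid = _ms_grid(a - 8 * s, a + 8 * s, spec.rt_span)
            scale = 10.0 ** rng.uniform(-1.5, 1.0)
            y = scale * _shape(grid, a, s, h, spec.peak_shape, spec.emg_tau)
            y = y + rng.normal(0.0, spec.major_noise_sd_frac * y.max(), y.size)
            y = np.clip(y, 0.0, None)
            apex_idx = int(np.argmax(y))
            features.append(MsFeature(fid, "pos", float(rng.uniform(150, 1200)),
                                      float(grid[apex_idx]), float(y[apex_idx]),
                                      Trace("XIC", grid, y, MS_RATE)))
            truth_features[fid] = {"kind": "major", "parent_peak": pi,
                                   "is_shape_major": True, "is_final_major": False}
            peak_fids.append(fid)
        for di in range(decoys):
            fid += 1
            if di % 2 == 0:   # retention-shifted copy
                shift = (spec.decoy_shift_min_fwhm + rng.uniform(0.0, 1.0)) * fwhm
                shift *= rng.choice([-1.0, 1.0])
                c = a + shift
                grid = _ms_grid(c - 8 * s, c + 8 * s, spec.rt_span)
                y = 10.0 ** rng.uniform(-1.5, 1.0) * _shape(
                    grid, c, s, h, spec.peak_shape, spec.emg_tau)
                kind = "decoy_shifted"
            else:             # shape-independent smooth signal under the peak
                grid = _ms_grid(a - 3 * s, a + 3 * s, spec.rt_span)
                y = 10.0 ** rng.uniform(-1.5, 1.0) * _smooth_random_shape(grid, rng)
                kind = "decoy_uncorrelated"
            y = y + rng.normal(0.0, spec.major_noise_sd_frac * max(y.max(), 1e-9), y.size)
            y = np.clip(y, 0.0, None)
            apex_idx = int(np.argmax(y))
            features.append(MsFeature(fid, "pos", float(rng.uniform(150, 1200)),
                                      float(grid[apex_idx]), float(y[apex_idx]),
                                      Trace("XIC", grid, y, MS_RATE)))
            truth_features[fid] = {"kind": kind, "parent_peak": pi,
                                   "is_shape_major": False, "is_final_major": False}
            peak_fids.append(fid)
        # designate exactly one species-level confident candidate for a
        # configurable fraction of peaks (among the planted majors)
        if rng.uniform() < spec.species_fraction and majors > 0:
            chosen = int(rng.choice([f for f in peak_fids
                                     if truth_features[f]["kind"] == "major"]))
            designated[pi] = chosen
            truth_features[chosen]["is_final_major"] = True
        else:
            designated[pi] = None

    # ---- annotations
    annotations: list[CandidateAnnotation] = []
    for f in features:
        info = truth_features[f.feature_id]
        pi = info["parent_peak"]
        if designated.get(pi) == f.feature_id:
            tax = 0.9
            conf = float(rng.uniform(*spec.confident_range))
        else:
            tax = float(rng.choice(tax_vals, p=tax_probs))
            conf = float(rng.uniform(*spec.confidence_distribution))
        level = _TAX_TO_LEVEL.get(tax, "none")
        pw, sc, cl = _PATHWAYS[int(rng.integers(len(_PATHWAYS)))]
        info["tax_score"] = tax
        info["confidence"] = conf
        annotations.append(CandidateAnnotation(
            feature_id=f.feature_id, rank=1, structure_id=f"STRUCT_{f.feature_id:05d}",
            molecular_formula=f"C{int(rng.integers(10, 40))}H{int(rng.integers(12, 60))}O{int(rng.integers(1, 12))}",
            npc_pathway=pw, npc_superclass=sc, npc_class=cl,
            taxonomic_distance_score=tax, final_score=conf,
            closest_organism=_ORGANISMS.get(level, "Unknown sp."), taxon_level=level))
        if rng.uniform() < 0.3:  # occasional lower-ranked alternate
            pw2, sc2, cl2 = _PATHWAYS[int(rng.integers(len(_PATHWAYS)))]
            annotations.append(CandidateAnnotation(
                feature_id=f.feature_id, rank=2,
                structure_id=f"STRUCT_{f.feature_id:05d}b",
                molecular_formula=f"C{int(rng.integers(10, 40))}H{int(rng.integers(12, 60))}O{int(rng.integers(1, 12))}",
                npc_pathway=pw2, npc_superclass=sc2, npc_class=cl2,
                taxonomic_distance_score=float(rng.choice(tax_vals, p=tax_probs)),
                final_score=float(rng.uniform(0.0, 0.5)),
                closest_organism="Unknown sp.", taxon_level="none"))

    # ---- toy molecular network: star per peak around the first feature
    net = nx.Graph()
    for f in features:
        net.add_node(f.feature_id, mz=f.mz, rt=f.rt_apex)
    by_peak: dict[int, list[int]] = {}
    for fid_, info in truth_features.items():
        by_peak.setdefault(info["parent_peak"], []).append(fid_)
    for fids in by_peak.values():
        hub = fids[0]
        for other in fids[1:]:
            net.add_edge(hub, other, type="ms2", weight=0.8)

    truth = GroundTruth(
        peaks=[{"apex": float(a), "sigma": float(s), "height": float(h),
                "area": float(h * s * math.sqrt(2 * math.pi))}
               for a, s, h in zip(apexes, sigmas, heights)],
        features=truth_features)
    chroms = ChromatogramSet(traces={"CAD": cad, "PDA": pda}, ionization_mode="pos")
    return FixtureBundle(chroms, features, annotations, net, truth)


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as mzML + feature/annotation TSV + GraphML + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mzml": write_fixture_mzml(bundle.chromatograms.traces.values(),
                                   out / "run.mzML"),
        "features": write_feature_table(bundle.features, out / "features.tsv"),
        "annotations": write_annotation_table(bundle.annotations,
                                              out / "annotations.tsv"),
        "network": write_network(bundle.network, out / "network.graphml"),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(
        {"peaks": bundle.truth.peaks,
         "features": {str(k): v for k, v in bundle.truth.features.items()}},
        indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths
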