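# Methods

`cadlink` automates a semiquantitative composition assessment of natural
extracts analysed on an LC system with three detectors in series: a
photodiode array (PDA), a Charged Aerosol Detector (CAD) and a
high-resolution mass spectrometer (MS). The CAD responds roughly
uniformly across compound classes, so the area of a CAD peak is a useful
proxy for the relative amount of the underlying analyte — something MS
intensities, dominated by ionization efficiency, cannot provide. The
package links untargeted MS features (with their annotations) to CAD
peaks, splitting the metabolome into a semiquantified "major" part and
the remaining "minor" part.

## Signal model and pretreatment

Each detector yields an intensity-versus-time trace; times are minutes
everywhere inside the package, converted once at the mzML boundary.
Because the detectors sit at different points of the flow path, constant
lags map the PDA and CAD axes onto the MS axis (defaults 0.090 and
0.055 min; the MS trails both). No dynamic time warping is attempted —
on the instrument geometry modelled here the lag is constant across the
run.

The CAD acquisition is configured to capture small signal changes and is
correspondingly noisy. Denoising is a brick-wall Fourier low-pass: the
forward DFT is taken and only the lowest `ceil(fraction * N)` components
(default fraction 0.01) are kept, together with their conjugate-symmetric
partners, so the output is real and the DC level (hence a constant
baseline) is preserved exactly. A hard cutoff with a single parameter was
chosen over a smooth window; with chromatographic peaks concentrated far
below the cutoff there is no visible Gibbs artefact, and `fraction = 1`
is the exact identity, which the tests pin to 1e-9.

Resolution enhancement subtracts a scaled second derivative (optionally
adding a fourth): `y - k2*y'' + k4*y''''`, derivatives by central
differences on the uniform grid with second-order one-sided stencils at
the edges. For a near-Gaussian peak of width sigma this narrows the full
width at half maximum while leaving the apex position and, up to boundary
terms, the integrated area unchanged (the integral of `y''` telescopes to
the boundary slopes). The default `k2 = (w/4)^2` is tied to a nominal
peak width `w` (default 0.1 min), which equals the classic `sigma^2/4`
choice when `sigma = w/4`. `k4` defaults to 0: the fourth-derivative term
buys little extra narrowing at these sampling rates and amplifies noise
quartically with the grid step.

Traces are resampled by linear interpolation to a uniform 2 Hz grid, the
approximate MS1 acquisition rate, so that CAD segments (natively ~60 Hz)
and feature XICs are defined on comparable grids; queries outside a
trace's span take the nearest edge value.

Two pretreated versions of the CAD trace are used downstream:

* **detection trace** — align, denoise, sharpen, resample: sharpening
  exists to separate partially co-eluting peaks before the simple
  one-dimensional peak picker runs;
* **linking trace** — align, denoise, resample, *no* sharpening: the MS
  XICs it is correlated with are unsharpened, and sharpening the 2 Hz
  XICs symmetrically instead would amplify their noise through the
  `1/h^2` factor of the discrete second derivative. In the noiseless
  limit this choice makes the CAD-versus-major-XIC correlation exactly 1,
  which the test suite uses as a sanity anchor.

## CAD peak picking and integration

The detection trace is one-dimensional, so simple rules suffice. Apexes
are local maxima (leftmost sample of a plateau); each peak's bounds run
to the nearest local minimum on either side, giving pairwise
non-overlapping peaks that share boundary samples at valleys. A peak is
kept if its apex height above the linear baseline through its two bound
samples is at least `min_snr` (default 5) times the noise level, and its
bounds span at least `min_width` (default 0.05 min).

The noise level is `1.4826 * MAD(diff(y)) / sqrt(2)` — a robust
estimator of white-noise sigma that ignores peaks because the first
difference of a slowly varying signal is small. It must be evaluated on
the **raw** trace: after low-pass filtering, adjacent-sample differences
shrink by design and the estimator would report a misleadingly small
level, letting residual-noise bumps through the gate. The pipeline
therefore estimates noise before pretreatment and passes it to the
detector.

Integration is the trapezoidal rule between the bounds minus the linear
baseline through the two bound intensities; a negative net area (a dip)
is clamped to zero with a warning. On planted Gaussians with >= 4 sigma
spacing and signal-to-noise >= 20 the tests require exact peak-count
recovery, apex within one sample, and area within 5% of
`h * sigma * sqrt(2*pi)`. Note that area is measured on the sharpened
trace between valley bounds, which clips the outermost tails; for the
default `k2` the bias is ~1–2% for isolated Gaussians and grows for
overlapped or edge peaks.

## Linking MS features to CAD peaks

A feature is a candidate of the unique CAD peak whose minima-to-minima
interval contains the feature's retention-time apex (a boundary tie goes
to the earlier peak; a feature outside all peaks is "minor" by default).
For each candidate, the CAD linking-trace segment and the feature's XIC
are cropped to the peak bounds, time-normalized affinely to [0, 1],
min-max scaled in intensity (a constant segment maps to zeros and can
never appear shape-correlated), resampled to a shared grid, and compared
by Pearson correlation with closest-point pairing (ties to the earlier
point). Min-max scaling does not change the Pearson value — it exists so
that segments are comparable when MS and CAD intensities differ by
orders of magnitude. The feature is "major" at the shape stage iff the
similarity reaches the threshold (default 0.8).

## Annotation filter cascade

Shape-correlated features still pile up under a CAD peak, so two further
filters act on the candidates' metadata (produced by external annotation
engines and consumed as input):

1. **taxonomic prioritization** — among the shape-majors under one peak,
   if any best-ranked candidate carries a taxonomic distance score of
   0.9 (structure already reported in the studied species), exactly those
   are kept; else any at 0.8 (same genus); below genus no prioritization
   is applied and all pass through. Score matching uses a 1e-9 tolerance
   rather than float equality.
2. **confidence filter** — a candidate survives only if its composite
   annotation score is strictly above 0.4. Scores above 1 survive but
   are flagged in the report as suspect (typically overfitting of the
   scoring model).

Demoted features are reclassified "minor", never deleted; the multiset
of feature ids is invariant through the cascade and the cascade is
idempotent. Per-stage counts (all linked -> shape -> +taxon ->
+confidence) are recorded for summary tables and alluvial plots; they
are non-increasing by construction.

## Reporting

Summary statistics average over peaks that retain at least one linked
feature at the given stage; means are rounded half-up to one decimal, the
precision of the printed tables this mirrors. Distinctness keys are the
stereochemistry-free structure id, the molecular-formula string and the
chemical-class label of each feature's best-ranked candidate. The
per-peak report lists every integrated peak — peaks with no surviving
candidate are flagged `unannotated` rather than dropped, since they are
the ones to prioritize for manual structure elucidation. Area fractions
are shares of the total integrated area. Pseudochromatogram bars reuse
the integrated areas bit-exactly (reporting never re-integrates);
treemap fractions split a peak's area equally among its retained
candidates and sum to 1; molecular-network nodes gain `cad_area`,
`status_final` and `npc_pathway` attributes, with minors at area 0.
Alluvial bins on candidate-structure counts per peak are 0 / 1 / 2 /
3–5 / >5.

## Synthetic study conditions

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as the package's reference conditions: 20 Gaussian
peaks (EMG tailing available) over a 20 min run, sigma 0.03–0.07 min,
apex heights 50–500 CAD units over white noise of sd 1 and a slow
one-period sinusoidal drift of amplitude 2; the CAD is sampled at 60 Hz
(~30x the MS rate, exercising the resampling path) on its own time axis,
shifted by the instrument lag. Each peak carries 2–3 "major" features
(parent shape x a log-uniform scale + 2% multiplicative-apex noise at
2 Hz) and 2–3 decoys, alternating retention-shifted copies (>= 2 FWHM
away) and smooth shape-independent signals under the peak. Exactly one
major per peak is designated the species-level confident candidate
(taxonomic score 0.9, confidence uniform on 0.5–0.95); all other
features draw taxonomic scores from {0.8, 0.6, 0.3} with weights
0.15/0.35/0.5 and confidence uniform on 0.05–0.9. One seeded generator
drives every draw, so a spec is byte-reproducible.

What the fixtures do *not* emulate: CAD response non-linearity and its
eluent-composition dependence (a power-function calibration and inverse
gradients are out of scope), adduct/fragment degeneracy among features,
retention drift between detectors beyond a constant lag, and heavy peak
overlap. Passing tests therefore demonstrate the correctness of the
workflow's logic and numerics under its stated assumptions, not
quantitative accuracy on real extracts.

## Numerical choices and edge cases

* Times strictly increasing, finite intensities, >= 2 points per trace;
  violated invariants raise at construction.
* Fourier denoising refuses nonuniform traces (resample first).
* Plateau apexes take the leftmost sample; boundary features go to the
  earlier peak; zero-variance normalized segments score similarity 0.
* Similarity needs >= 3 pairable points; an XIC that does not usably
  overlap its peak's bounds contributes no shape evidence (similarity 0).
* Empty inputs degrade gracefully: empty peak lists, header-only tables
  and empty reports are all legal.
* Problem sizes in the tests (20-peak reference fixture, 100-seed cascade
  randomization, 5-peak detection oracles) keep the whole suite in the
  low seconds while still estimating the recovery rates with ~50 planted
  majors and ~50 decoys per run.

## Known limitations

* Areas from the sharpened trace are biased low by tail clipping
  (~1–2% isolated, worse when overlapped); an unsharpened integration
  pass would trade peak separation for accuracy.
* Each feature belongs to at most one CAD peak by apex containment, even
  if its XIC spans several peaks.
* Positive and negative ionization runs are processed independently
  against their own CAD trace; no cross-mode merge policy is built in.
* The semiquantitation inherits every CAD caveat (response differences
  between structures, eluent-composition effects); reported areas are
  relative, not calibrated amounts.
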