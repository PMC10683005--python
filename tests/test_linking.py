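"""Feature-to-peak attribution and peak-shape similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadlink.linking import (LinkConfig, assign_candidates,
                             classify_major_minor, normalize_pair,
                             shape_similarity)
from cadlink.models import CadPeak, MsFeature, Trace

from conftest import gaussian_trace


def make_feature(fid, rt, trace):
    return MsFeature(fid, "pos", 300.0 + fid, rt, 10.0, trace)


def xic_from(trace, scale=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = scale * trace.intensities + rng.normal(0.0, noise, len(trace))
    return Trace("XIC", trace.times, np.clip(y, 0, None))


PEAKS = [
    CadPeak(1, 10.0, 9.8, 10.2, 50.0, 5.0),
    CadPeak(2, 10.5, 10.2, 10.8, 40.0, 4.0),
]


class TestAssign:
    def test_containment(self):
        tr = gaussian_trace(apex=10.0)
        feats = [make_feature(1, 10.05, tr)]
        assert assign_candidates(feats, PEAKS) == {1: [1], 2: []}

    def test_outside_all_peaks_unassigned(self):
        tr = gaussian_trace(apex=12.0)
        feats = [make_feature(1, 12.0, tr)]
        assert assign_candidates(feats, PEAKS) == {1: [], 2: []}

    def test_shared_boundary_goes_to_earlier_peak(self):
        tr = gaussian_trace(apex=10.2)
        feats = [make_feature(1, 10.2, tr)]
        assert assign_candidates(feats, PEAKS) == {1: [1], 2: []}

    def test_many_features_under_one_peak(self):
        tr = gaussian_trace(apex=10.0)
        feats = [make_feature(i, 9.85 + 0.002 * i, tr) for i in range(128)]
        cands = assign_candidates(feats, PEAKS)
        assert len(cands[1]) == 128


class TestNormalizePair:
    def test_identity_on_equal_segments(self):
        cad = gaussian_trace(apex=10.0, span=0.3)
        a, b = normalize_pair(cad, cad.with_values(detector_id="XIC"), PEAKS[0])
        assert np.allclose(a.intensities, b.intensities)
        assert a.times[0] == 0.0 and a.times[-1] == 1.0
        assert a.intensities.min() == 0.0 and a.intensities.max() == 1.0

    def test_multiplicative_scale_invariant(self):
        cad = gaussian_trace(apex=10.0, span=0.3)
        xic = cad.with_values(intensities=3.7 * cad.intensities, detector_id="XIC")
        a, b = normalize_pair(cad, xic, PEAKS[0])
        assert np.allclose(a.intensities, b.intensities, atol=1e-12)

    def test_constant_segment_all_zero(self):
        cad = gaussian_trace(apex=10.0, span=0.3)
        xic = cad.with_values(intensities=np.full(len(cad), 2.0), detector_id="XIC")
        _, b = normalize_pair(cad, xic, PEAKS[0])
        assert np.all(b.intensities == 0.0)

    def test_empty_overlap_rejected(self):
        cad = gaussian_trace(apex=10.0, span=0.3)
        xic = gaussian_trace(apex=15.0, span=0.3, detector="XIC")
        with pytest.raises(ValueError, match="overlap"):
            normalize_pair(cad, xic, PEAKS[0])


class TestShapeSimilarity:
    def test_self_similarity_is_one(self):
        a, _ = normalize_pair(gaussian_trace(apex=10.0, span=0.3),
                              gaussian_trace(apex=10.0, span=0.3, detector="XIC"),
                              PEAKS[0])
        assert shape_similarity(a, a) == pytest.approx(1.0)

    def test_affine_transform_is_one(self):
        a, _ = normalize_pair(gaussian_trace(apex=10.0, span=0.3),
                              gaussian_trace(apex=10.0, span=0.3, detector="XIC"),
                              PEAKS[0])
        b = a.with_values(intensities=2.5 * a.intensities + 0.3)
        assert shape_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_time_reversal_of_monotone_segment_is_minus_one(self):
        # Pearson((1,2,3), (3,2,1)) = -1 exactly
        a = Trace("CAD", np.array([0.0, 0.5, 1.0]), np.array([1.0, 2.0, 3.0]))
        b = Trace("XIC", np.array([0.0, 0.5, 1.0]), np.array([3.0, 2.0, 1.0]))
        assert shape_similarity(a, b) == pytest.approx(-1.0)

    def test_symmetry_on_equal_grids(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 21)
        a = Trace("CAD", t, rng.random(21))
        b = Trace("XIC", t, rng.random(21))
        assert shape_similarity(a, b) == pytest.approx(shape_similarity(b, a))

    def test_zero_variance_scores_zero(self):
        t = np.linspace(0, 1, 11)
        a = Trace("CAD", t, np.linspace(0, 1, 11))
        b = Trace("XIC", t, np.zeros(11))
        assert shape_similarity(a, b) == 0.0

    def test_closest_point_pairing_different_grids(self):
        t_fine = np.linspace(0.0, 1.0, 121)
        t_coarse = np.linspace(0.0, 1.0, 13)
        shape = lambda t: np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2)
        a = Trace("CAD", t_fine, shape(t_fine))
        b = Trace("XIC", t_coarse, shape(t_coarse))
        assert shape_similarity(a, b) >= 0.999

    def test_too_few_points_rejected(self):
        a = Trace("CAD", np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            shape_similarity(a, a)

    @given(c1=st.floats(0.1, 10), c2=st.floats(-5, 5))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_minmax_scaling_does_not_change_pearson(self, c1, c2):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 1, 31)
        y = rng.random(31)
        a = Trace("CAD", t, y)
        b = Trace("XIC", t, c1 * y + c2)
        assert shape_similarity(a, b) == pytest.approx(1.0, abs=1e-9)


class TestClassify:
    def _setup(self):
        cad = gaussian_trace(apex=10.0, sigma=0.05, height=50.0, span=1.0)
        peak = CadPeak(1, 10.0, 9.8, 10.2, 50.0, 5.0)
        return cad, [peak]

    def test_partition_every_feature_once(self, default_bundle, default_result):
        link_ids = sorted(lk.feature_id for lk in default_result.links)
        assert link_ids == sorted(f.feature_id for f in default_bundle.features)

    def test_correlated_candidate_is_major(self):
        cad, peaks = self._setup()
        f = make_feature(1, 10.0, xic_from(cad.crop(9.5, 10.5), scale=0.3))
        [lk] = classify_major_minor([f], peaks, cad)
        assert lk.status_shape == "major"
        assert lk.similarity >= 0.8

    def test_below_threshold_keeps_peak_and_similarity(self):
        cad, peaks = self._setup()
        rng = np.random.default_rng(4)
        seg = cad.crop(9.5, 10.5)
        noise = Trace("XIC", seg.times, np.abs(rng.normal(5, 1, len(seg))))
        f = make_feature(1, 10.0, noise)
        [lk] = classify_major_minor([f], peaks, cad)
        assert lk.status_shape == "minor"
        assert lk.peak_id == 1
        assert lk.similarity is not None and lk.similarity < 0.8

    def test_outside_peak_is_minor_with_no_peak(self):
        cad, peaks = self._setup()
        f = make_feature(1, 12.0, gaussian_trace(apex=12.0, detector="XIC"))
        [lk] = classify_major_minor([f], peaks, cad)
        assert (lk.peak_id, lk.similarity, lk.status_shape) == (None, None, "minor")

    def test_threshold_monotonicity(self, default_bundle):
        from cadlink.pretreatment import PretreatmentConfig, pretreat
        from cadlink.peaks import detect_peaks
        b = default_bundle
        cfg = PretreatmentConfig()
        cad = pretreat(b.chromatograms.cad(), cfg.lag_cad_to_ms, cfg)
        peaks = detect_peaks(cad)
        cad_link = pretreat(b.chromatograms.cad(), cfg.lag_cad_to_ms, cfg,
                            sharpen=False)
        n_major = []
        for thr in [0.5, 0.65, 0.8, 0.9, 0.95]:
            links = classify_major_minor(b.features, peaks, cad_link,
                                         LinkConfig(similarity_threshold=thr))
            n_major.append(sum(lk.status_shape == "major" for lk in links))
        assert n_major == sorted(n_major, reverse=True)

    def test_planted_majors_and_decoys_separated(self, default_bundle, default_result):
        truth = default_bundle.truth.features
        majors = [lk for lk in default_result.links
                  if truth[lk.feature_id]["is_shape_major"]]
        decoys = [lk for lk in default_result.links
                  if not truth[lk.feature_id]["is_shape_major"]]
        major_rate = np.mean([lk.status_shape == "major" for lk in majors])
        decoy_rate = np.mean([lk.status_shape == "minor" for lk in decoys])
        assert major_rate >= 0.95
        assert decoy_rate >= 0.95
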