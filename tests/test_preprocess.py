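import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmhkit import metrics, phantom, preprocess
from wmhkit.types import (
    ConfigurationError,
    DegenerateBoundsError,
    EmptyClassError,
    LabelMap,
    Volume,
    ZeroVarianceError,
)


def vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=float), spacing)


def toy_labeled(values, class_id=1):
    """Tiny volume whose first voxels carry the given class values."""
    data = np.zeros((len(values), 1, 1))
    data[:, 0, 0] = values
    labels = np.full((len(values), 1, 1), class_id, dtype=np.int16)
    return vol(data), LabelMap(labels)


class TestClassStats:
    def test_constant_region(self):
        v, lab = toy_labeled([5.0, 5.0, 5.0])
        s = preprocess.estimate_class_stats(v, lab, 1)
        assert (s.mean, s.sd, s.max_intensity) == (5.0, 0.0, 5.0)

    def test_hand_worked_mean_and_population_sd(self):
        v, lab = toy_labeled([1.0, 2.0, 3.0, 4.0])
        s = preprocess.estimate_class_stats(v, lab, 1)
        assert s.mean == pytest.approx(2.5)
        assert s.sd == pytest.approx(np.sqrt(1.25))  # divisor N, not N-1
        assert s.n == 4
        assert s.counts.sum() == s.n

    def test_absent_class_raises(self):
        v, lab = toy_labeled([1.0, 2.0])
        with pytest.raises(EmptyClassError):
            preprocess.estimate_class_stats(v, lab, 9)


class TestPdfMode:
    def test_dominant_value_recovered_within_half_bin(self):
        values = np.concatenate([np.full(90, 100.0), np.linspace(0, 200, 10)])
        v = vol(values.reshape(-1, 1, 1))
        mode = preprocess.pdf_mode(v, np.ones(v.shape, bool), n_bins=64)
        assert abs(mode - 100.0) <= 0.5 * (200.0 / 64)

    def test_bimodal_mixture_picks_dominant_mode(self, rng):
        sample = np.concatenate(
            [rng.normal(50, 1, 700), rng.normal(150, 1, 300)]
        )
        v = vol(sample.reshape(-1, 1, 1))
        counts, edges = np.histogram(sample, bins=64)  # independent oracle
        expected = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert preprocess.pdf_mode(v, np.ones(v.shape, bool), 64) == pytest.approx(expected)

    def test_tie_broken_toward_lower_bin(self):
        # two bins with identical counts: 0s and 10s, 2 bins over [0, 10]
        v = vol(np.array([0.0, 0.0, 10.0, 10.0]).reshape(-1, 1, 1))
        mode = preprocess.pdf_mode(v, np.ones(v.shape, bool), n_bins=2)
        assert mode == pytest.approx(2.5)  # lower bin center

    def test_empty_mask_raises(self):
        v = vol(np.zeros((2, 2, 2)))
        with pytest.raises(EmptyClassError):
            preprocess.pdf_mode(v, np.zeros((2, 2, 2), bool))


class TestTransformBounds:
    @staticmethod
    def stats(mean, sd):
        return preprocess.ClassStats(1, 1, mean, sd, np.array([0.0, 1.0]), np.array([1]), mean)

    def test_hand_worked_bounds(self):
        b = preprocess.transform_bounds(self.stats(120, 10), self.stats(140, 5), 100, 150)
        assert b.p_min == pytest.approx(40.0)
        assert b.p_max == pytest.approx(105.0)

    def test_no_shift_when_mode_equals_brain_max(self):
        b = preprocess.transform_bounds(self.stats(120, 10), self.stats(140, 5), 100, 100)
        assert b.p_min == pytest.approx(120 - 30)

    def test_degenerate_bounds_raise(self):
        with pytest.raises(DegenerateBoundsError):
            preprocess.transform_bounds(self.stats(100, 0), self.stats(100, 0), 100, 100)


class TestPiecewiseRescale:
    def bounds(self, lo=10.0, hi=20.0):
        return preprocess.TransformBounds(lo, hi, 0, 0, 0)

    def test_endpoints_and_midpoint(self):
        v = vol(np.array([10.0, 15.0, 20.0]).reshape(-1, 1, 1))
        out = preprocess.piecewise_rescale(v, self.bounds()).data.ravel()
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(128.0)
        assert out[2] == pytest.approx(255.0)

    def test_out_of_range_maps_to_zero(self):
        v = vol(np.array([9.9, 20.1]).reshape(-1, 1, 1))
        assert np.all(preprocess.piecewise_rescale(v, self.bounds()).data == 0)

    @given(st.lists(st.floats(10.0, 20.0), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_monotone_on_window(self, values):
        v = vol(np.array(sorted(values)).reshape(-1, 1, 1))
        out = preprocess.piecewise_rescale(v, self.bounds()).data.ravel()
        assert np.all(np.diff(out) >= 0)


class TestDenoise:
    def test_constant_volume_unchanged(self):
        v = vol(np.full((5, 5, 5), 7.0))
        out = preprocess.denoise(v, median_window=3, gaussian_sigma=0.5)
        assert np.allclose(out.data, 7.0)

    def test_impulse_removed_by_median(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 100.0
        out = preprocess.denoise(vol(data), median_window=3)
        assert out.data[2, 2, 2] == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            preprocess.denoise(vol(np.zeros((3, 3, 3))), median_window=4)

    def test_gaussian_kernel_normalized(self):
        k = preprocess._gaussian_kernel_1d(0.8)
        assert k.sum() == pytest.approx(1.0)


class TestNormalize:
    def test_output_spans_unit_interval(self, rng):
        v = vol(rng.normal(100, 10, (6, 6, 6)))
        out = preprocess.normalize(v, np.ones(v.shape, bool))
        assert out.data.min() == pytest.approx(0.0)
        assert out.data.max() == pytest.approx(1.0)

    def test_zscore_mean_zero_over_mask(self, rng):
        v = vol(rng.normal(50, 5, (6, 6, 6)))
        mask = np.ones(v.shape, bool)
        values = v.data[mask]
        z = (v.data - values.mean()) / values.std()
        assert abs(z[mask].mean()) < 1e-9

    def test_constant_input_raises(self):
        with pytest.raises(ZeroVarianceError):
            preprocess.normalize(vol(np.full((4, 4, 4), 3.0)), np.ones((4, 4, 4), bool))

    def test_min_max_absorbs_zscore_affine(self, rng):
        # the final min-max rescale cancels any affine z-score, so the
        # percentile-clipped statistics change mu_B/sigma_B but not the
        # normalized output — the clip matters only to stages that consume
        # the statistics themselves
        data = rng.normal(100, 5, (8, 8, 8))
        data[0, 0, 0] = 1e5  # extreme outlier
        v = vol(data)
        clipped = preprocess.normalize(v, np.ones(v.shape, bool), percentile_clip=(2, 95))
        plain = preprocess.normalize(v, np.ones(v.shape, bool))
        assert np.allclose(clipped.data, plain.data)
        assert clipped.data.min() == 0.0 and clipped.data.max() == 1.0


class TestCandidateAndMorphology:
    def test_k_zero_selects_above_mean(self, rng):
        v = vol(rng.normal(0, 1, (6, 6, 6)))
        mask = np.ones(v.shape, bool)
        cand = preprocess.candidate_wmh(v, mask, 0.0)
        assert np.array_equal(cand, v.data >= v.data.mean())

    def test_huge_k_gives_empty_mask(self, rng):
        v = vol(rng.normal(0, 1, (6, 6, 6)))
        assert not preprocess.candidate_wmh(v, np.ones(v.shape, bool), 1e6).any()

    def test_lesions_separable_at_k3(self, rng):
        data = rng.normal(100, 5, (16, 16, 16))
        lesion = np.zeros((16, 16, 16), bool)
        lesion[6:10, 6:10, 6:10] = True
        data[lesion] = 100 + 8 * 5  # 8 sigma above brain mean
        cand = preprocess.candidate_wmh(vol(data), np.ones((16,) * 3, bool), 3.0)
        assert np.all(cand[lesion])
        assert cand[~lesion].mean() < 0.05

    def test_definite_suspected_band_split(self, rng):
        data = rng.normal(0, 1, (12, 12, 12))
        v = vol(data)
        mask = np.ones(v.shape, bool)
        definite, suspected = preprocess.split_definite_suspected(v, mask, 1.0, 2.0)
        mu, sigma = data.mean(), data.std()
        assert np.array_equal(definite, data >= mu + 2 * sigma)
        assert not np.any(definite & suspected)
        assert np.array_equal(definite | suspected, data >= mu + 1 * sigma)
        with pytest.raises(ConfigurationError):
            preprocess.split_definite_suspected(v, mask, 2.0, 1.0)

    def test_single_voxel_removed_by_opening(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert not preprocess.morph_open(m, 1).any()

    def test_large_cube_survives_box_opening(self):
        # a 9^3 cube opened with a 3^3 box element is exactly restored
        m = np.zeros((13, 13, 13), bool)
        m[2:11, 2:11, 2:11] = True
        assert np.array_equal(preprocess.morph_open(m, 1, element=np.ones((3, 3, 3), bool)), m)

    def test_empty_mask_stays_empty(self):
        assert not preprocess.morph_open(np.zeros((4, 4, 4), bool), 1).any()

    def test_opening_idempotent_and_below_dilation(self, rng):
        from scipy import ndimage

        m = rng.random((12, 12, 12)) > 0.7
        opened = preprocess.morph_open(m, 1)
        assert np.array_equal(preprocess.morph_open(opened, 1), opened)
        dilated = ndimage.binary_dilation(m)
        assert np.all(~opened | dilated)  # opened subset of dilation


class TestVolumeAndComposition:
    def test_lesion_volume_hand_cases(self):
        m = np.zeros((10, 10, 1), bool)
        m.flat[:100] = True
        assert preprocess.lesion_volume(m, (1, 1, 1)) == pytest.approx(100.0)
        m8 = np.zeros((2, 2, 2), bool)
        m8[:] = True
        assert preprocess.lesion_volume(m8, (0.5, 0.5, 1.0)) == pytest.approx(2.0)
        assert preprocess.lesion_volume(np.zeros((3, 3, 3), bool), (1, 1, 1)) == 0.0

    def test_compose_weights(self, rng):
        v = vol(rng.random((2, 2, 1)))
        wmh = rng.random((2, 2, 1)) > 0.5
        vessel = rng.random((2, 2, 1)) > 0.5
        p = preprocess.SegmentationParams(w_B=1, w_T=0, w_V=0)
        assert np.array_equal(preprocess.compose_input(v, wmh, vessel, p).data, v.data)
        p = preprocess.SegmentationParams(w_B=0, w_T=1, w_V=0)
        assert np.array_equal(
            preprocess.compose_input(v, wmh, vessel, p).data, wmh.astype(float)
        )
        p = preprocess.SegmentationParams(w_B=0.5, w_T=0.25, w_V=0.25)
        expected = 0.5 * v.data + 0.25 * wmh + 0.25 * vessel
        assert np.allclose(preprocess.compose_input(v, wmh, vessel, p).data, expected)


class TestStandardizeGeometry:
    def test_odd_matrix_reaches_target_size(self):
        v = Volume(np.zeros((181, 217, 4)), spacing=(0.5, 0.5, 3.0))
        out = preprocess.standardize_geometry(v)
        assert out.shape == (200, 200, 4)
        assert out.spacing == (0.5, 0.5, 3.0)

    def test_already_standard_is_unchanged(self, rng):
        v = Volume(rng.random((200, 200, 3)), spacing=(0.5, 0.5, 2.0))
        out = preprocess.standardize_geometry(v)
        assert np.allclose(out.data, v.data)

    def test_center_crop_preserves_centroid(self):
        data = np.zeros((256, 256, 1))
        data[126:130, 126:130, 0] = 1.0
        out = preprocess.standardize_geometry(Volume(data, spacing=(0.5, 0.5, 1.0)))
        assert out.shape == (200, 200, 1)
        idx = np.argwhere(out.data > 0.5)
        centroid = idx[:, :2].mean(axis=0)
        assert np.all(np.abs(centroid - 99.5) <= 1.0)


class TestPipelineRecovery:
    def test_zero_noise_pipeline_recovers_lesions(self, separable_phantom_pair):
        clean, calib = separable_phantom_pair
        brain = phantom.brain_mask_of(clean)
        stats_T = preprocess.estimate_class_stats(calib.volume, calib.labels, phantom.DEFINITE)
        stats_V = preprocess.estimate_class_stats(calib.volume, calib.labels, phantom.VESSEL)
        stats_B = preprocess.estimate_class_stats(calib.volume, calib.labels, phantom.BRAIN)
        n_pdf = preprocess.pdf_mode(clean.volume, brain)
        bounds = preprocess.transform_bounds(stats_T, stats_V, n_pdf, stats_B.max_intensity)
        stages = preprocess.run_pipeline_stages(
            clean.volume, brain, bounds, preprocess.SegmentationParams(k=2.0)
        )
        truth = clean.labels.data == phantom.DEFINITE
        best = max(
            metrics.dsc(truth, preprocess.morph_open(
                preprocess.candidate_wmh(stages["normalized"], brain, k), 1))
            for k in np.linspace(0.5, 4.0, 8)
        )
        assert best >= 0.95

    def test_truth_mask_volume_matches_phantom_ground_truth(self, default_phantom):
        truth = default_phantom.labels.data == phantom.DEFINITE
        assert preprocess.lesion_volume(truth, default_phantom.volume.spacing) == (
            default_phantom.true_lesion_volume
        )
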