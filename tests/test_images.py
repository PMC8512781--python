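import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vowelbci.io import Recording, TrialSet, electrode_pairs
from vowelbci.images import (
    WindowingSpec,
    build_image_set,
    normalize_image,
    pair_difference_spectrum,
    segment_windows,
)
from vowelbci.synthetic import SyntheticConfig, dataset_trialsets


class TestWindowing:
    def test_default_stride_is_ten(self):
        assert WindowingSpec().stride == 64 - 54 == 10

    @pytest.mark.parametrize(
        "T,expected", [(12800, 1274), (64, 1), (73, 1), (74, 2), (128, 7)]
    )
    def test_window_counts(self, T, expected):
        windows = segment_windows(np.zeros((2, T)))
        assert len(windows) == expected
        assert all(w.shape == (2, 64) for w in windows)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_windows(np.zeros((2, 63)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(T=st.integers(64, 600), overlap=st.sampled_from([0.0, 0.5, 0.85]))
    def test_count_matches_brute_force_enumeration(self, T, overlap):
        spec = WindowingSpec(overlap_fraction=overlap)
        got = len(segment_windows(np.zeros((1, T)), spec))
        brute = sum(1 for s in range(T) if s % spec.stride == 0 and s + 64 <= T)
        assert got == brute

    def test_windows_tile_the_signal(self):
        x = np.arange(200.0)[None, :]
        spec = WindowingSpec()
        for k, w in enumerate(segment_windows(x, spec)):
            np.testing.assert_array_equal(w[0], x[0, k * 10 : k * 10 + 64])


class TestPairDifference:
    def test_identical_channels_give_zero(self):
        w = np.tile(np.sin(np.arange(64)), (3, 1))
        out = pair_difference_spectrum(w)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_output_shape_14_channels(self):
        out = pair_difference_spectrum(np.random.default_rng(0).normal(size=(14, 64)))
        assert out.shape == (32, 91)

    def test_cosine_line_amplitude(self):
        # channel i = unit cosine at 16 Hz (bin 8 of a 64-point DFT at 128 Hz):
        # the (i, j) column is 32 (= N/2) at row 8 and ~0 elsewhere; columns
        # not involving channel i are all zero
        w = np.zeros((4, 64))
        w[1] = np.cos(2 * np.pi * 16 * np.arange(64) / 128.0)
        pairs = electrode_pairs(4)
        out = pair_difference_spectrum(w, pairs)
        col = pairs.index((1, 2))
        assert np.isclose(out[8, col], 32.0, atol=1e-9)
        mask = np.ones(32, bool)
        mask[8] = False
        np.testing.assert_allclose(out[mask, col], 0.0, atol=1e-9)
        col_no_i = pairs.index((2, 3))
        np.testing.assert_allclose(out[:, col_no_i], 0.0, atol=1e-9)

    def test_pair_symmetry(self):
        # |A - B| = |B - A|: swapping two channels leaves the pair column unchanged
        rng = np.random.default_rng(1)
        w = rng.normal(size=(3, 64))
        swapped = w[[1, 0, 2]]
        out = pair_difference_spectrum(w)
        out_sw = pair_difference_spectrum(swapped)
        np.testing.assert_allclose(out[:, 0], out_sw[:, 0], atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            pair_difference_spectrum(np.zeros((2, 32)))


class TestNormalize:
    def test_affine_map(self):
        m = np.array([[2.0, 10.0], [6.0, 2.0]])
        out = normalize_image(m)
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.5, 0.0]])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_image(np.zeros((3, 3))), np.zeros((3, 3)))
        np.testing.assert_array_equal(normalize_image(np.full((2, 2), 7.0)), np.zeros((2, 2)))

    def test_non_finite_rejected(self):
        m = np.ones((2, 2))
        m[0, 0] = np.inf
        with pytest.raises(ValueError):
            normalize_image(m)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_spans_unit_interval(self, seed):
        w = np.random.default_rng(seed).normal(size=(5, 64))
        out = normalize_image(pair_difference_spectrum(w))
        assert np.isclose(out.min(), 0.0) and np.isclose(out.max(), 1.0)


class TestBuildImageSet:
    def test_study_shaped_counts(self):
        # 25 trials x 512 samples per vowel, concatenated, stride 10:
        # 1274 images per vowel, 6370 total
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=25, n_channels=14, seed=7)
        ts = dataset_trialsets(cfg, subjects=[0])[0]
        imageset = build_image_set(ts)
        counts = imageset.class_counts()
        assert all(counts[v] == 1274 for v in "aeiou")
        assert len(imageset) == 6370
        assert imageset.images[0].shape == (32, 91)

    def test_single_minimal_trial(self):
        rec = Recording(np.random.default_rng(0).normal(size=(2, 64)), 128.0, ("E1", "E2"))
        imageset = build_image_set(TrialSet([rec], ["a"], [0]))
        assert len(imageset) == 1
        assert imageset.images[0].shape == (32, 1)

    def test_empty_trialset(self):
        assert len(build_image_set(TrialSet([], [], []))) == 0

    def test_all_values_in_unit_interval(self, small_imageset):
        X, y, _ = small_imageset.stack()
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert X.shape[1:] == (32, 28)  # 8-channel montage: C(8,2) = 28 pairs

    def test_filter_applies_per_trial_or_per_window(self):
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=1, n_channels=4, seed=9)
        ts = dataset_trialsets(cfg, subjects=[0], vowels=["a"])[0]
        calls = []

        def spy(x):
            calls.append(x.shape)
            return x

        build_image_set(ts, filter=spy)
        assert calls == [(4, 512)]  # whole trial
        calls.clear()
        build_image_set(ts, filter=spy, filter_per_window=True)
        assert len(calls) == 45 and calls[0] == (4, 64)  # each window

    def test_per_trial_windowing_mode(self):
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=2, n_channels=4, seed=8)
        ts = dataset_trialsets(cfg, subjects=[0], vowels=["a"])[0]
        spec = WindowingSpec(concatenate_trials=False)
        imageset = build_image_set(ts, spec)
        # per trial: floor((512-64)/10)+1 = 45 windows; 2 trials
        assert len(imageset) == 90
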