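import numpy as np
import pytest

from vowelbci.memd import (
    APITMEMD,
    DirectionSet,
    ResidueReached,
    SiftConfig,
    apit_memd,
    envelope_mean,
    hammersley_sphere,
    memd,
    principal_direction,
    relocate_directions,
    select_band_imfs,
    sift_imf,
    spectral_centroid,
)
from vowelbci.synthetic import SyntheticConfig, generate_trial

FS = 128.0


def tone(freq, n=512, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / FS + phase)


class TestHammersley:
    def test_unit_norm(self):
        for K, dim in [(8, 2), (64, 14), (33, 6)]:
            v = hammersley_sphere(K, dim).vectors
            np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_pairwise_distinct(self):
        v = hammersley_sphere(64, 14).vectors
        gram = v @ v.T
        np.fill_diagonal(gram, 0.0)
        assert gram.max() < 1.0 - 1e-9  # minimum pairwise angle > 0

    def test_deterministic(self):
        a = hammersley_sphere(32, 6).vectors
        b = hammersley_sphere(32, 6).vectors
        np.testing.assert_array_equal(a, b)

    def test_dim_guard(self):
        with pytest.raises(ValueError):
            hammersley_sphere(8, 1)


class TestPrincipalDirection:
    def test_single_active_channel(self):
        frame = np.zeros((3, 50))
        frame[0] = np.linspace(0, 1, 50)
        w1, _ = principal_direction(frame)
        np.testing.assert_allclose(w1, [1.0, 0.0, 0.0], atol=1e-12)

    def test_perfectly_correlated_channels(self):
        x = np.sin(np.linspace(0, 7, 200))
        w1, eigvals = principal_direction(np.vstack([x, x]))
        np.testing.assert_allclose(w1, np.array([1.0, 1.0]) / np.sqrt(2), atol=1e-12)
        assert eigvals[0] >= eigvals[1]

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            principal_direction(np.ones((3, 40)))

    def test_isotropic_noise_no_crash(self):
        rng = np.random.default_rng(0)
        w1, _ = principal_direction(rng.normal(size=(4, 5000)))
        assert np.isclose(np.linalg.norm(w1), 1.0)
        # sign convention: first nonzero component positive
        assert w1[np.flatnonzero(np.abs(w1) > 1e-12)[0]] > 0


class TestRelocation:
    def setup_method(self):
        self.uniform = hammersley_sphere(16, 3)
        self.w1 = np.array([0.0, 0.0, 1.0])

    def test_alpha_zero_is_identity(self):
        out = relocate_directions(self.uniform, self.w1, 0.0)
        np.testing.assert_allclose(out.vectors, self.uniform.vectors, atol=1e-12)

    def test_large_alpha_collapses_to_anchors(self):
        out = relocate_directions(self.uniform, self.w1, 1e6)
        cos = out.vectors @ self.w1
        angles = np.arccos(np.clip(np.abs(cos), -1, 1))
        assert angles.max() < 1e-3

    def test_half_toward_each_anchor(self):
        out = relocate_directions(self.uniform, self.w1, 10.0)
        cos = out.vectors @ self.w1
        assert (cos > 0).sum() == 8
        assert (cos < 0).sum() == 8

    def test_outputs_unit_norm(self):
        out = relocate_directions(self.uniform, self.w1, 0.7)
        np.testing.assert_allclose(np.linalg.norm(out.vectors, axis=1), 1.0, atol=1e-12)


class TestEnvelopeMean:
    def test_constant_frame_is_residue(self):
        dirs = hammersley_sphere(8, 2)
        state = envelope_mean(np.ones((2, 64)), dirs)
        assert state.residue_reached

    def test_sinusoid_mean_near_zero_in_interior(self):
        frame = np.vstack([tone(10.0), np.zeros(512)])
        state = envelope_mean(frame, hammersley_sphere(16, 2))
        assert not state.residue_reached
        interior = state.mean[0, 64:-64]
        assert np.abs(interior).max() < 0.05  # < 5% of unit amplitude

    def test_single_direction_mean_is_that_envelope(self):
        frame = np.vstack([tone(10.0), tone(10.0, phase=1.0)])
        d = DirectionSet(np.array([[1.0, 0.0]]))
        state = envelope_mean(frame, d)
        assert state.n_usable_directions == 1
        assert state.mean.shape == frame.shape


class TestSifting:
    def test_clean_oscillation_extracted_in_one_mode(self):
        # common 10 Hz carrier across channels: IMF1 carries >= 99% energy
        frame = np.vstack([tone(10.0), tone(10.0, phase=0.7), tone(10.0, phase=1.9)])
        imf, deflated = sift_imf(frame, SiftConfig())
        assert np.sum(imf**2) / np.sum(frame**2) >= 0.99

    def test_telescoping_identity(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(size=(3, 256))
        imf, deflated = sift_imf(frame, SiftConfig())
        np.testing.assert_allclose(frame, imf + deflated, atol=1e-12)

    def test_linear_trend_raises_residue(self):
        trend = np.vstack([np.linspace(0, 1, 256), np.linspace(2, 0, 256)])
        with pytest.raises(ResidueReached):
            sift_imf(trend, SiftConfig())

    def test_fixed_sift_count_mode(self):
        rng = np.random.default_rng(4)
        frame = rng.normal(size=(2, 256))
        imf, _ = sift_imf(frame, SiftConfig(fixed_sifts=3))
        assert imf.shape == frame.shape


class TestDecomposition:
    def test_completeness(self):
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=1, n_channels=6, seed=5)
        x = generate_trial(cfg, 0, "e", 0).samples
        stack = apit_memd(x, SiftConfig())
        rel = np.abs(stack.reconstruct() - x).max() / np.abs(x).max()
        assert rel < 1e-8

    def test_two_tone_separation(self):
        frame = np.vstack(
            [tone(30.0) + tone(8.0), tone(30.0, 512, 0.5) + tone(8.0, 512, 0.3)]
        )
        stack = apit_memd(frame, SiftConfig())
        c = [spectral_centroid(imf, FS) for imf in stack.imfs]
        assert abs(c[0] - 30.0) < 5.0
        assert any(abs(ci - 8.0) < 3.0 for ci in c[1:])

    def test_alpha_zero_matches_uniform_memd(self):
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=1, n_channels=4, seed=6)
        x = generate_trial(cfg, 0, "u", 0).samples[:, :256]
        a = apit_memd(x, SiftConfig(alpha=0.0))
        b = memd(x, SiftConfig())
        assert a.n_imfs == b.n_imfs
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_allclose(ia, ib, atol=1e-10)

    def test_frequency_ordering_mostly_monotone(self):
        # spectral centroid non-increasing across IMFs, <= 1 inversion per
        # decomposition, over 10 random broadband inputs
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(3, 384)).cumsum(axis=1)  # brown-ish noise
            x += rng.normal(size=x.shape)
            stack = apit_memd(x, SiftConfig())
            c = [spectral_centroid(imf, FS) for imf in stack.imfs]
            inversions = sum(1 for a, b in zip(c, c[1:]) if b > a + 1e-9)
            assert inversions <= 1

    def test_direction_count_preserved(self):
        dirs = hammersley_sphere(32, 5)
        out = relocate_directions(dirs, np.eye(5)[0], 0.5)
        assert out.vectors.shape == (32, 5)


class TestBandSelection:
    def test_full_sum_plus_residue_recovers_input(self):
        cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=1, n_channels=4, seed=7)
        x = generate_trial(cfg, 0, "i", 0).samples
        stack = apit_memd(x, SiftConfig())
        total = select_band_imfs(stack, stack.n_imfs) + stack.residue
        assert np.abs(total - x).max() / np.abs(x).max() < 1e-8

    def test_k2_is_elementwise_sum(self):
        from vowelbci.memd import IMFStack

        a, b = np.full((2, 8), 1.5), np.full((2, 8), -0.25)
        stack = IMFStack([a, b, np.zeros((2, 8))], np.zeros((2, 8)))
        np.testing.assert_array_equal(select_band_imfs(stack, 2), a + b)

    def test_k_exceeding_stack_errors(self):
        from vowelbci.memd import IMFStack

        stack = IMFStack([np.zeros((2, 8))], np.zeros((2, 8)))
        with pytest.raises(ValueError, match="1"):
            select_band_imfs(stack, 3)

    def test_band_filter_keeps_high_drops_slow(self):
        # 30 + 8 + 1 Hz three-tone input: the first-two-IMF filter keeps the
        # 30 Hz band and rejects the 1 Hz trend component
        def band_power(x, lo, hi):
            spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
            freqs = np.fft.rfftfreq(x.shape[1], 1 / FS)
            return spec[:, (freqs >= lo) & (freqs <= hi)].sum()

        frame = np.vstack(
            [
                tone(30.0, 1024) + tone(8.0, 1024) + tone(1.0, 1024),
                tone(30.0, 1024, 0.4) + tone(8.0, 1024, 0.2) + tone(1.0, 1024, 0.9),
            ]
        )
        filtered = APITMEMD(n_keep=2).transform_frame(frame)
        keep30 = band_power(filtered, 25, 35) / band_power(frame, 25, 35)
        keep1 = band_power(filtered, 0.5, 1.5) / band_power(frame, 0.5, 1.5)
        assert keep30 >= 0.90
        assert keep1 <= 0.10

    def test_transformer_is_sklearn_compatible(self):
        est = APITMEMD(alpha=0.3, n_keep=1)
        assert est.get_params()["alpha"] == 0.3
        est.set_params(alpha=0.0)
        assert est.get_params()["alpha"] == 0.0
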