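import math

import numpy as np
import pytest

from semggan import dcgan1d
from semggan.dcgan1d import (
    DiscriminatorSpec, GeneratorSpec, SmoothingSpec, bce_loss,
    build_discriminator, build_generator, dtw_distance, fft_magnitude,
    make_minibatch_kernel, minibatch_features, optimal_discriminator,
    smooth_labels, wavelet_bank,
)
from semggan.features import FeatureSpec, mdwt


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss([1.0], [1.0]) == pytest.approx(0.0, abs=1e-6)

    def test_half_prediction_is_ln2(self):
        assert bce_loss([0.5], [1.0]) == pytest.approx(math.log(2), rel=1e-9)

    def test_hand_evaluated_batch(self):
        expected = -0.5 * (math.log(0.9) + math.log(0.9))
        assert bce_loss([0.9, 0.1], [1, 0]) == pytest.approx(expected, rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([0.5, 0.5], [1.0])


class TestLabelSmoothing:
    def test_one_sided_defaults(self):
        np.testing.assert_allclose(smooth_labels([1, 1, 0]), [0.9, 0.9, 0.0])

    def test_negatives_untouched(self):
        np.testing.assert_allclose(smooth_labels([0, 0, 0]), [0.0, 0.0, 0.0])

    def test_identity_when_unsmoothed(self):
        spec = SmoothingSpec(alpha=1.0, beta=0.0)
        np.testing.assert_allclose(smooth_labels([1, 0, 1], spec), [1, 0, 1])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SmoothingSpec(alpha=0.5, beta=0.6)


class TestOptimalDiscriminator:
    def test_equal_densities(self):
        assert optimal_discriminator(1.0, 1.0) == pytest.approx(0.45)

    def test_pure_data(self):
        assert optimal_discriminator(2.0, 0.0) == pytest.approx(0.9)

    def test_pure_model(self):
        assert optimal_discriminator(0.0, 3.0) == pytest.approx(0.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            optimal_discriminator(0.0, 0.0)


# independent memoized-recursion oracle for DTW
def dtw_oracle(a, b):
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return math.inf
        return abs(a[i - 1] - b[j - 1]) + min(rec(i - 1, j), rec(i - 1, j - 1),
                                              rec(i, j - 1))

    return rec(len(a), len(b))


class TestDTW:
    def test_identity(self):
        assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_evaluated(self):
        assert dtw_distance([0, 0], [1, 1]) == pytest.approx(2.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.standard_normal(8)
            b = rng.standard_normal(11)
            d = dtw_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(dtw_distance(b, a), rel=1e-12)

    def test_matches_recursion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n, m = rng.integers(2, 13, size=2)
            a = tuple(rng.standard_normal(n))
            b = tuple(rng.standard_normal(m))
            assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b),
                                                       rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestFFTMagnitude:
    def test_constant_signal_concentrates_at_dc(self):
        m = fft_magnitude(np.full(64, 3.0))
        assert m[0] == pytest.approx(3.0 * 64)
        assert np.all(m[1:] < 1e-9)

    def test_tone_bin_location(self):
        t = np.arange(1000) / 2000.0
        m = fft_magnitude(np.sin(2 * np.pi * 100.0 * t))
        assert np.argmax(m) == 50  # k = f*N/fs

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(256)
        X = np.fft.fft(x)
        assert np.sum(np.abs(X) ** 2) == pytest.approx(256 * np.sum(x**2),
                                                       rel=1e-6)
        # one-sided magnitudes agree with the two-sided ones
        np.testing.assert_allclose(fft_magnitude(x), np.abs(X[:129]), rtol=1e-9)

    def test_output_length(self):
        assert len(fft_magnitude(np.zeros(256))) == 129


class TestWaveletBank:
    def test_zero_maps_to_zero(self):
        assert np.all(wavelet_bank(np.zeros(256)) == 0.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        np.testing.assert_allclose(wavelet_bank(2.5 * x), 2.5 * wavelet_bank(x),
                                   rtol=1e-10)

    def test_marginals_recoverable_from_bank(self):
        """Summed |coefficients| per level equal the mDWT feature."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal(256)
        spec = FeatureSpec()
        bank = wavelet_bank(x, spec)
        # reconstruct per-level slices: level 1 first
        lengths = []
        n = 256
        import pywt
        w = pywt.Wavelet(spec.wavelet_name)
        for _ in range(spec.wavelet_levels):
            n = pywt.dwt_coeff_len(n, w.dec_len, mode="symmetric")
            lengths.append(n)
        marginals = []
        pos = 0
        for L in lengths:
            marginals.append(np.sum(np.abs(bank[pos:pos + L])))
            pos += L
        np.testing.assert_allclose(marginals, mdwt(x, spec), rtol=1e-10)

    def test_fixed_length_for_fixed_input_length(self):
        rng = np.random.default_rng(7)
        lens = {len(wavelet_bank(rng.standard_normal(256))) for _ in range(5)}
        assert len(lens) == 1


class TestMinibatchFeatures:
    def test_identical_batch_scores_one(self):
        batch = np.tile(np.linspace(-1, 1, 32), (4, 1))
        out = minibatch_features(batch, seed=0)
        np.testing.assert_allclose(out, 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        batch = rng.standard_normal((6, 32))
        kernel = make_minibatch_kernel(32, 8, 8, seed=1)
        out = minibatch_features(batch, kernel)
        perm = rng.permutation(6)
        out_p = minibatch_features(batch[perm], kernel)
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-12)

    def test_outlier_scores_minimum(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(32)
        batch = np.stack([base + 0.01 * rng.standard_normal(32),
                          base + 0.01 * rng.standard_normal(32),
                          base + 25.0])
        out = minibatch_features(batch, seed=2)
        assert np.argmin(out) == 2

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError):
            minibatch_features(np.zeros((1, 8)))


class TestNetworkContracts:
    def test_generator_range_and_length(self):
        spec = GeneratorSpec(output_length=256)
        gen = build_generator(spec, seed=0)
        z = np.random.default_rng(1).standard_normal((5, spec.latent_dim))
        out = gen.forward(z, training=False)
        assert out.shape == (5, 256)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_generator_init_deterministic(self):
        spec = GeneratorSpec(output_length=128)
        a = build_generator(spec, seed=3)
        b = build_generator(spec, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_discriminator_outputs_probabilities(self):
        spec = DiscriminatorSpec()
        disc = build_discriminator(spec, input_length=256, seed=0)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 256))
        side = rng.standard_normal((4, disc.side_dim))
        p = disc.forward(x, side, training=False)
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))

    def test_discriminator_init_deterministic(self):
        spec = DiscriminatorSpec()
        a = build_discriminator(spec, input_length=128, seed=7)
        b = build_discriminator(spec, input_length=128, seed=7)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_bad_output_length_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(output_length=250)  # not divisible by 2^3
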