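import numpy as np
import pandas as pd
import pytest

from semggan import protocol_sim as ps
from semggan import sigproc
from semggan.evalsuite import (
    STRENGTH_BANDS, UndefinedStatisticError, augmentation_sweep, c2st,
    classify, correlation_strength, feature_correlation, mantel_test,
)
from semggan.features import feature_matrix


def _random_symmetric(rng, n):
    a = rng.standard_normal((n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class TestFeatureCorrelation:
    def test_collinear_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x + 1, rng.standard_normal(50)])
        corr = feature_correlation(X).to_numpy()
        assert corr[0, 1] == pytest.approx(1.0)

    def test_negated_column(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        X = np.column_stack([x, -x, rng.standard_normal(50)])
        corr = feature_correlation(X).to_numpy()
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4))
        corr = feature_correlation(X).to_numpy()
        # oracle: covariance / sigma_i sigma_j from explicit sums
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(X)
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(corr, cov / np.outer(sd, sd), atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal((20, 3)), np.full(20, 7.0)])
        with pytest.warns(UserWarning):
            corr = feature_correlation(X)
        assert corr.shape == (3, 3)


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(4)
        dx = _random_symmetric(rng, 8)
        res = mantel_test(dx, dx, permutations=1000, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(5)
        dx = _random_symmetric(rng, 8)
        dy = 3.0 * dx + 2.0
        np.fill_diagonal(dy, 1.0)  # diagonal ignored by the statistic
        res = mantel_test(dx, dy, permutations=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_scikit_bio_on_distance_matrices(self):
        """Cross-check statistic against an independent implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((7, 3))
        dx = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dy = np.abs(pts[:, None, 0] - pts[None, :, 0])
        r_skbio, _, _ = skbio_stats.mantel(dx, dy, method="pearson",
                                           permutations=0)
        res = mantel_test(dx, dy, permutations=10, seed=0)
        assert res.r == pytest.approx(float(r_skbio), rel=1e-9)

    def test_null_calibration(self):
        """Under independence, P(p < 0.05) stays within 0.05 +- 0.02."""
        rng = np.random.default_rng(0)
        hits = 0
        n_pairs = 500
        for i in range(n_pairs):
            dx = _random_symmetric(rng, 8)
            dy = _random_symmetric(rng, 8)
            res = mantel_test(dx, dy, permutations=99, seed=1000 + i)
            if res.p_value < 0.05:
                hits += 1
        assert abs(hits / n_pairs - 0.05) <= 0.02

    def test_zero_variance_triangle_rejected(self):
        dx = np.ones((5, 5))
        with pytest.raises(UndefinedStatisticError):
            mantel_test(dx, dx, permutations=10, seed=0)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            mantel_test(_random_symmetric(rng, 5), _random_symmetric(rng, 6))

    def test_strength_bands(self):
        assert correlation_strength(0.1) == "very weak"
        assert correlation_strength(0.5) == "medium"
        assert correlation_strength(-0.9) == "very strong"
        assert len(STRENGTH_BANDS) == 5


class TestClassify:
    def _separable(self, n=60):
        rng = np.random.default_rng(8)
        X0 = rng.standard_normal((n, 4))
        X1 = rng.standard_normal((n, 4)) + 20.0
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        return X, y

    @pytest.mark.parametrize("clf", ["adaboost", "bagging", "svm", "logistic"])
    def test_separable_classes_perfect(self, clf):
        X, y = self._separable()
        assert classify(X, y, classifier=clf, seed=0) == 1.0

    def test_shuffled_labels_at_chance(self):
        """Permutation null: mean accuracy 0.5 +- 0.05 over 50 repeats."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 5))
        accs = []
        for i in range(50):
            y = rng.permutation([0] * 50 + [1] * 50)
            accs.append(classify(X, y, classifier="logistic", seed=i))
        assert abs(np.mean(accs) - 0.5) <= 0.05

    def test_deterministic_per_seed(self):
        X, y = self._separable()
        X += np.random.default_rng(1).standard_normal(X.shape) * 15
        a = classify(X, y, classifier="adaboost", seed=3)
        b = classify(X, y, classifier="adaboost", seed=3)
        assert a == b

    def test_single_class_rejected(self):
        X = np.zeros((20, 3))
        with pytest.raises(ValueError):
            classify(X, np.zeros(20), classifier="svm")

    def test_unknown_classifier_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError):
            classify(X, y, classifier="parzen")


class TestC2ST:
    def test_null_calibration_identical_gaussians(self):
        """Mean held-out accuracy approximately 50% when G = R."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            R = rng.standard_normal((1000, 10))
            G = rng.standard_normal((1000, 10))
            accs.append(c2st(R, G, seed=seed).accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.03

    def test_separated_gaussians_detected(self):
        rng = np.random.default_rng(0)
        R = rng.standard_normal((500, 10))
        G = rng.standard_normal((500, 10)) + 10.0
        assert c2st(R, G, seed=0).accuracy >= 0.99

    def test_duplicate_sample_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((1000, 10))
        res = c2st(X[:500], X[500:], seed=1)
        # binomial error at n_te=200: 3 sigma approximately 0.105
        assert abs(res.accuracy - 0.5) <= 0.11

    def test_split_sizes(self):
        rng = np.random.default_rng(2)
        res = c2st(rng.standard_normal((100, 3)),
                   rng.standard_normal((100, 3)), seed=0)
        assert res.n_test == 40 and res.n_train == 160

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            c2st(np.zeros((0, 3)), np.zeros((10, 3)))


class TestAugmentationSweep:
    @pytest.fixture(scope="class")
    def sessions(self):
        proto = ps.ProtocolSpec(2000.0, 1, 3, 1.0, 0.5, 4)
        models = ps.make_default_gesture_models(3, 1, seed=10)
        real = ps.simulate_session(proto, models, seed=10)
        syn = ps.simulate_session(proto, models, seed=20)
        return real, syn

    def test_zero_fraction_equals_plain_classification(self, sessions):
        real, syn = sessions
        grid = sigproc.WindowGrid(window_lengths=(200,),
                                  increment_fractions=(0.5,))
        sweep = augmentation_sweep(real, syn, grid=grid, classifier="svm",
                                   seed=5)
        wins = sigproc.segment_windows(real, 200, 0.5)
        fm = feature_matrix(wins)
        plain = classify(fm, classifier="svm", seed=5)
        cell = sweep.loc[sweep.synthetic_fraction == 0.0, "accuracy"].iloc[0]
        assert cell == plain  # bit-for-bit under the shared seed

    def test_grid_is_complete(self, sessions):
        real, syn = sessions
        grid = sigproc.WindowGrid(window_lengths=(200, 400),
                                  increment_fractions=(0.5, 1.0))
        sweep = augmentation_sweep(real, syn, grid=grid, seed=0)
        assert len(sweep) == 2 * 2 * 5
        assert set(sweep.synthetic_fraction) == {0.0, 0.25, 0.5, 0.75, 1.0}
        assert not sweep.accuracy.isna().any()
        assert ((sweep.accuracy >= 0) & (sweep.accuracy <= 1)).all()

    def test_ideal_augmenter_improves_data_poor_classification(self):
        """Fresh simulator draws as an ideal generator: adding 100% synthetic
        windows should not hurt average accuracy of a data-poor classifier."""
        proto = ps.ProtocolSpec(2000.0, 1, 4, 1.0, 0.5, 2)  # 2 reps/gesture
        models = ps.make_default_gesture_models(4, 1, seed=2)
        grid = sigproc.WindowGrid(window_lengths=(200,),
                                  increment_fractions=(1.0,))
        acc0, acc100 = [], []
        for seed in range(10):
            real = ps.simulate_session(proto, models, seed=100 + seed)
            syn = ps.simulate_session(proto, models, seed=200 + seed)
            sweep = augmentation_sweep(real, syn, grid=grid,
                                       fractions=(0.0, 1.0), seed=seed)
            acc0.append(
                sweep.loc[sweep.synthetic_fraction == 0.0, "accuracy"].iloc[0])
            acc100.append(
                sweep.loc[sweep.synthetic_fraction == 1.0, "accuracy"].iloc[0])
        assert np.mean(acc100) >= np.mean(acc0)

    def test_insufficient_synthetic_pool_rejected(self, sessions):
        real, _ = sessions
        proto = ps.ProtocolSpec(2000.0, 1, 3, 1.0, 0.5, 1)
        models = ps.make_default_gesture_models(3, 1, seed=10)
        tiny = ps.simulate_session(proto, models, seed=30)
        grid = sigproc.WindowGrid(window_lengths=(200,),
                                  increment_fractions=(0.25,))
        with pytest.raises(ValueError):
            augmentation_sweep(real, tiny, grid=grid, fractions=(1.0,), seed=0)
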