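import numpy as np
import pandas as pd
import pytest

from lipopanel import (
    SyntheticConfig,
    compute_vip,
    cross_validated_q2,
    fit_oplsda,
    generate_dataset,
    generate_null_dataset,
    impute_and_log,
    permutation_test,
    top_vip,
)
from lipopanel.oplsda import predict


def _random_problem(seed, n=24, p=6, effect=1.5):
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    X[:, 1] -= effect * y
    return X, y


class TestFit:
    def test_no_orthogonal_structure_matches_pls1(self):
        """With n_ortho=0 the predictive weights equal sklearn's PLS1 first component."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_problem(0)
        model = fit_oplsda(X, y, n_ortho=0, scale=None)
        pls = PLSRegression(n_components=1, scale=False)
        pls.fit(X - X.mean(axis=0), y - y.mean())
        w_ref = pls.x_weights_[:, 0]
        w_ref /= np.linalg.norm(w_ref)
        sign = np.sign(w_ref @ model.weights) or 1.0
        np.testing.assert_allclose(model.weights * sign, w_ref, atol=1e-8)

    def test_perfect_predictor_gives_r2y_near_one(self):
        # y itself as a column: after one orthogonal component strips the
        # noise direction, the predictive component recovers y exactly
        rng = np.random.default_rng(1)
        y = np.repeat([0.0, 1.0], 10)
        X = np.column_stack([y, rng.normal(size=20)])
        model = fit_oplsda(X, y, n_ortho=1)
        assert model.r2y >= 0.99

    def test_fit_is_deterministic(self):
        X, y = _random_problem(2)
        m1 = fit_oplsda(X, y, n_ortho=1)
        m2 = fit_oplsda(X, y, n_ortho=1)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.r2y == m2.r2y

    def test_orthogonal_scores_uncorrelated_with_class(self):
        X, y = _random_problem(3, n=40, p=10)
        model = fit_oplsda(X, y, n_ortho=2)
        yc = y - y.mean()
        for a in range(model.n_ortho):
            r = np.corrcoef(model.ortho_scores[:, a], yc)[0, 1]
            assert abs(r) < 1e-8

    def test_excess_orthogonal_components_error(self):
        X, y = _random_problem(4, n=8, p=3)
        with pytest.raises(ValueError):
            fit_oplsda(X, y, n_ortho=5)

    def test_constant_feature_dropped_with_warning(self):
        X, y = _random_problem(5)
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_oplsda(X, y, n_ortho=0)
        assert model.weights.size == X.shape[1] - 1

    def test_r2y_bounds_and_predictive_score_sign_invariance(self):
        X, y = _random_problem(6, n=30, p=8)
        m0 = fit_oplsda(X, y, n_ortho=0)
        assert 0.0 <= m0.r2y <= 1.0
        # projecting the training data reproduces the training scores
        yhat = predict(m0, X)
        np.testing.assert_allclose(yhat, m0.c * m0.scores + m0.y_mean, atol=1e-10)


class TestVip:
    def test_single_feature_normalization_limit(self):
        # two identical-information features: symmetry forces VIP = 1 each
        rng = np.random.default_rng(7)
        y = np.repeat([0.0, 1.0], 12)
        base = y + 0.1 * rng.normal(size=24)
        X = np.column_stack([base, base + 1e-12 * rng.normal(size=24)])
        model = fit_oplsda(X, y, n_ortho=0)
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-4)

    def test_formula_from_model_internals(self):
        X, y = _random_problem(8, n=20, p=3)
        model = fit_oplsda(X, y, n_ortho=1)
        w = model.weights
        expected = np.sqrt(3) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(compute_vip(model), expected, atol=1e-12)

    def test_sum_of_squares_equals_feature_count(self):
        for seed in range(5):
            X, y = _random_problem(seed, n=26, p=9)
            model = fit_oplsda(X, y, n_ortho=1)
            assert np.sum(model.vip**2) == pytest.approx(9, rel=1e-9)

    def test_top_vip_ordering_and_overflow(self):
        X, y = _random_problem(9, p=5)
        Xdf = pd.DataFrame(X, columns=[f"{j+1}POS" for j in range(5)])
        model = fit_oplsda(Xdf, y, n_ortho=0)
        top = top_vip(model, k=3)
        assert len(top) == 3
        assert list(top.values) == sorted(top.values, reverse=True)
        with pytest.warns(UserWarning, match="exceeds"):
            everything = top_vip(model, k=10)
        assert set(everything.index) == set(Xdf.columns)

    def test_planted_markers_reach_top20(self, small_dataset):
        table, truth = small_dataset
        log = impute_and_log(table)
        model = fit_oplsda(log.abundances, log.y, n_ortho=1)
        top = top_vip(model, k=20)
        for fid in truth["strong"]:
            assert fid in set(top.index)


class TestQ2AndPermutation:
    def test_q2_high_on_planted_signal(self):
        # signal-bearing feature set: autoscaling gives every feature equal
        # variance, so predictive ability depends on the planted:noise ratio
        cfg = SyntheticConfig(n_case=90, n_control=30, n_features=120, n_weak=6, seed=7)
        table, _ = generate_dataset(cfg)
        log = impute_and_log(table)
        q2 = cross_validated_q2(log.abundances, log.y, n_ortho=1, folds=7, seed=0)
        assert q2 > 0.5

    def test_q2_low_on_permuted_labels(self, small_dataset):
        table, _ = small_dataset
        log = impute_and_log(table)
        rng = np.random.default_rng(0)
        yp = rng.permutation(log.y)
        q2 = cross_validated_q2(log.abundances, yp, n_ortho=1, folds=7, seed=0)
        assert q2 <= 0.1

    def test_q2_deterministic_given_seed(self):
        X, y = _random_problem(10, n=30, p=6)
        assert cross_validated_q2(X, y, seed=5) == cross_validated_q2(X, y, seed=5)

    def test_permutation_p_floor_on_strong_signal(self, small_dataset):
        table, _ = small_dataset
        log = impute_and_log(table)
        res = permutation_test(log.abundances, log.y, n_ortho=1, n_permutations=100, seed=0)
        assert res.p_q2 == pytest.approx(1 / 101)
        assert res.observed_q2 > max(res.permuted_q2)

    def test_zero_permutations_rejected(self):
        X, y = _random_problem(11)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_permutations=0)

    def test_permuted_q2_stochastically_below_planted_q2(self):
        cfg = SyntheticConfig(n_case=30, n_control=10, n_features=40, n_weak=2, seed=31,
                              missing_rate=0.0)
        table, _ = generate_dataset(cfg)
        log = impute_and_log(table)
        rng = np.random.default_rng(0)
        q2_signal = cross_validated_q2(log.abundances, log.y, folds=5, seed=1)
        perm_q2 = [
            cross_validated_q2(log.abundances, rng.permutation(log.y), folds=5, seed=i)
            for i in range(20)
        ]
        assert q2_signal > np.quantile(perm_q2, 0.95)
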