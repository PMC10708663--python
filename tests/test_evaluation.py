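import numpy as np
import pytest

from hsicalib.evaluation import (
    EvaluationPair,
    MetricsReport,
    cross_validate,
    kennard_stone_split,
    pearson_matrix,
    r_squared,
    rer,
    rmse,
    rpd,
    rpd_category,
)


class TestKennardStone:
    def test_study_scale_four_to_one(self, rng):
        X = rng.normal(size=(187, 16))
        split = kennard_stone_split(X)
        assert len(split.calibration_ids) == 149
        assert len(split.test_ids) == 38

    def test_hand_traced_one_dimensional_example(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        split = kennard_stone_split(X, 4 / 5)
        # start with extremes {0, 10}; then 3 (max-min distance); then the
        # tie between 1 and 2 breaks to the lower index
        assert list(split.calibration_ids) == [0, 4, 3, 1]
        assert list(split.test_ids) == [2]

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            kennard_stone_split(rng.normal(size=(4, 3)))

    def test_disjoint_and_exhaustive(self, rng):
        X = rng.normal(size=(41, 5))
        split = kennard_stone_split(X)
        union = np.sort(np.concatenate([split.calibration_ids, split.test_ids]))
        np.testing.assert_array_equal(union, np.arange(41))

    def test_non_finite_features_rejected(self):
        X = np.ones((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            kennard_stone_split(X)


class TestPointMetrics:
    def test_rmse_examples(self):
        assert rmse(EvaluationPair([1, 2], [1, 2])) == 0.0
        assert rmse(EvaluationPair([0, 0], [3, 4])) == pytest.approx(np.sqrt(12.5))
        assert rmse(EvaluationPair([1], [4])) == pytest.approx(3.0)

    def test_r_squared_examples(self):
        assert r_squared(EvaluationPair([1, 2, 3], [1, 2, 3])) == pytest.approx(1.0)
        assert r_squared(EvaluationPair([1, 2, 3], [2, 2, 2])) == pytest.approx(0.0)
        assert r_squared(EvaluationPair([1, 2, 3], [1, 2, 4])) == pytest.approx(0.5)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(EvaluationPair([2, 2, 2], [1, 2, 3]))

    def test_metrics_match_brute_force_loops(self, rng):
        """Vectorized rmse / r_squared vs naive accumulation, 1e-12."""
        for _ in range(20):
            n = int(rng.integers(2, 60))
            c = rng.normal(size=n)
            chat = c + rng.normal(scale=0.3, size=n)
            sq = sum((a - b) ** 2 for a, b in zip(chat, c))
            brute_rmse = (sq / n) ** 0.5
            cbar = sum(c) / n
            brute_r2 = 1 - sq / sum((v - cbar) ** 2 for v in c)
            pair = EvaluationPair(c, chat)
            assert abs(rmse(pair) - brute_rmse) < 1e-12
            assert abs(r_squared(pair) - brute_r2) < 1e-12

    def test_rpd_examples(self):
        refs = np.array([1.0, 2.0, 3.0])  # sample sd = 1
        assert rpd(refs, 1.0) == pytest.approx(1.0)
        assert rpd(refs, 0.5) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            rpd(refs, 0.0)

    def test_rpd_categories(self):
        assert "limited" in rpd_category(1.0)
        assert rpd_category(6.324) == "excellent (>3)"
        assert "1.5-2.0" in rpd_category(1.7)
        assert "2.0-2.5" in rpd_category(2.2)
        assert "2.5-3.0" in rpd_category(2.7)

    def test_rer_examples(self):
        assert rer(2.064, 0.223, 0.017) == pytest.approx(108.294, abs=5e-4)
        assert rer(0.064, 0.001, 0.028) == pytest.approx(2.250, abs=5e-4)
        assert rer(1.0, 1.0, 0.1) == 0.0
        with pytest.raises(ValueError):
            rer(1.0, 0.0, 0.0)


class TestPearson:
    def test_self_correlation_unit_diagonal(self, rng):
        C = rng.normal(size=(30, 4))
        M = pearson_matrix(C)
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T)
        assert np.all(np.abs(M) <= 1 + 1e-12)

    def test_anticorrelated_pair(self, rng):
        x = rng.normal(size=50)
        M = pearson_matrix(np.column_stack([x, -x + 0.0]))
        assert M[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(np.column_stack([np.ones(5), np.arange(5.0)]))


def make_identity_oracle(X_all, Y_all):
    """Factory for a 'model' that knows the true target of every row."""
    table = {tuple(row): y for row, y in zip(X_all, np.atleast_2d(Y_all.T).T)}

    class _IdentityOracle:
        def fit(self, X, Y):
            return self

        def predict(self, X):
            return np.array([table[tuple(row)] for row in X])

    return _IdentityOracle


class _ConstantModel:
    def fit(self, X, Y):
        self._c = np.mean(Y, axis=0)
        return self

    def predict(self, X):
        return np.tile(self._c, (len(X), 1))


class TestCrossValidate:
    def test_perfect_oracle_gives_zero_rmsecv(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 2))
        oracle = make_identity_oracle(X, Y)
        rmsecv, rcv2 = cross_validate(oracle, X, Y, folds=5, seed=0)
        np.testing.assert_allclose(rmsecv, 0.0, atol=1e-12)
        np.testing.assert_allclose(rcv2, 1.0, atol=1e-12)

    def test_loo_fold_sizes(self, rng):
        from sklearn.model_selection import KFold

        n = 9
        sizes = [len(te) for _, te in KFold(n, shuffle=True, random_state=0).split(np.arange(n))]
        assert sizes == [1] * n
        X = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, 1))
        rmsecv, _ = cross_validate(make_identity_oracle(X, Y), X, Y, folds=n, seed=0)
        np.testing.assert_allclose(rmsecv, 0.0, atol=1e-12)

    def test_constant_factory_has_nonpositive_rcv2(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 1))
        _, rcv2 = cross_validate(_ConstantModel, X, Y, folds=5, seed=0)
        assert np.all(rcv2 <= 0.0)

    def test_invalid_folds_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        Y = rng.normal(size=(10,))
        with pytest.raises(ValueError):
            cross_validate(_ConstantModel, X, Y, folds=1)
        with pytest.raises(ValueError):
            cross_validate(_ConstantModel, X, Y, folds=11)


class TestMetricsReport:
    def test_report_layout_and_values(self, rng):
        y_cal = rng.normal(size=(40, 2)) + 5
        y_test = rng.normal(size=(10, 2)) + 5
        report = MetricsReport.from_predictions(
            ("a", "b"), y_cal, y_cal + 0.1, y_test, y_test + 0.2
        )
        frame = report.to_frame()
        assert list(frame.index) == ["a", "b"]
        for col in ("Rc2", "RMSEC", "Rp2", "RMSEP", "RER", "RPD"):
            assert col in frame.columns
        np.testing.assert_allclose(report.rmsec, 0.1, atol=1e-9)
        np.testing.assert_allclose(report.rmsep, 0.2, atol=1e-9)
        # RER consistency: calibration range / RMSEP
        for k in range(2):
            expected = (y_cal[:, k].max() - y_cal[:, k].min()) / report.rmsep[k]
            assert report.rer[k] == pytest.approx(expected)
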