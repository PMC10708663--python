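import numpy as np
import pytest

from hsicalib.band_selection import (
    cars_retention_schedule,
    cars_select,
    spa_select,
    uve_select,
)
from hsicalib.baseline_models import PLSRModel


def informative_data(rng, n=300, p=40, informative=(10, 25), noise=0.05):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    for j in informative:
        beta[j] = 3.0
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestCARSSchedule:
    def test_endpoints(self):
        r = cars_retention_schedule(50, 128)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(2.0 / 128)  # = 0.015625

    def test_monotone_decreasing(self):
        r = cars_retention_schedule(30, 64)
        assert np.all(np.diff(r) < 0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            cars_retention_schedule(1, 10)
        with pytest.raises(ValueError):
            cars_retention_schedule(10, 1)


class TestCARS:
    def test_informative_bands_recovered_across_seeds(self):
        """Strong-coefficient bands survive in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X, y = informative_data(rng, n=300, p=40, informative=(10, 25))
            sel = cars_select(X, y, n_runs=30, cv_folds=5, seed=seed,
                              n_components=5)
            if {10, 25} <= set(sel.selected_band_indices):
                hits += 1
        assert hits >= 9

    def test_two_band_floor(self, rng):
        X = rng.normal(size=(50, 2))
        y = X @ np.array([1.0, -1.0])
        sel = cars_select(X, y, n_runs=10, cv_folds=5, seed=0, n_components=2)
        assert set(sel.selected_band_indices) == {0, 1}

    def test_kept_fraction_non_increasing(self, rng):
        X, y = informative_data(rng, n=120, p=30, informative=(4, 17))
        sel = cars_select(X, y, n_runs=15, cv_folds=4, seed=3, n_components=4)
        fracs = [h["kept_fraction"] for h in sel.history]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_seeded_reproducibility(self, rng):
        X, y = informative_data(rng, n=80, p=20, informative=(3, 11))
        a = cars_select(X, y, n_runs=10, cv_folds=4, seed=7, n_components=3)
        b = cars_select(X, y, n_runs=10, cv_folds=4, seed=7, n_components=3)
        np.testing.assert_array_equal(a.selected_band_indices,
                                      b.selected_band_indices)
        assert a.history == b.history

    def test_preconditions(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            cars_select(X, y, n_runs=1)
        with pytest.raises(ValueError):
            cars_select(X[:, :1], y)


class TestSPA:
    def test_identity_matrix_hand_trace(self):
        X = np.eye(3)
        sel = spa_select(X, k_max=3, start=0)
        assert list(sel.selected_band_indices) == [0, 1, 2]

    def test_duplicate_column_never_selected_twice(self, rng):
        base = rng.normal(size=(20, 4))
        X = np.column_stack([base, base[:, 1]])  # column 4 duplicates column 1
        sel = spa_select(X, k_max=5, start=0)
        idx = list(sel.selected_band_indices)
        assert not (1 in idx and 4 in idx)

    def test_k_max_one_returns_start(self, rng):
        X = rng.normal(size=(10, 6))
        sel = spa_select(X, k_max=1, start=3)
        assert list(sel.selected_band_indices) == [3]

    def test_orthonormal_columns_y_in_span_selected_first(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(30, 6)))
        y = 2.5 * Q[:, 4]
        sel = spa_select(Q, k_max=3, start=4, y=y, cv_folds=3)
        assert sel.selected_band_indices[0] == 4

    def test_validation_prunes_chain(self, rng):
        X, y = informative_data(rng, n=100, p=12, informative=(3,), noise=0.01)
        sel = spa_select(X, k_max=8, start=3, y=y, cv_folds=4)
        assert 3 in sel.selected_band_indices
        assert len(sel.selected_band_indices) <= 8


class TestUVE:
    def test_informative_variable_retained(self, rng):
        X, y = informative_data(rng, n=120, p=15, informative=(4,), noise=0.01)
        sel = uve_select(X, y, n_components=4, seed=0)
        assert 4 in sel.selected_band_indices

    def test_noise_replica_columns_mostly_eliminated(self):
        """Pure-noise columns are cut at >= 90% on a 300-sample simulation."""
        rng = np.random.default_rng(42)
        n, p_inf, p_noise = 300, 5, 25
        Xs = rng.normal(size=(n, p_inf))
        y = Xs @ rng.uniform(1, 2, size=p_inf)
        X = np.column_stack([Xs, rng.normal(size=(n, p_noise))])
        sel = uve_select(X, y, n_components=5, seed=1)
        kept_noise = [j for j in sel.selected_band_indices if j >= p_inf]
        assert len(kept_noise) <= 0.1 * p_noise

    def test_zero_variance_coefficient_eliminated(self, rng):
        # a constant column never enters the PLS solution: coefficient 0 with
        # sd 0 -> stability 0 -> eliminated
        X = rng.normal(size=(40, 5))
        X[:, 2] = 0.0
        y = X[:, 0] + 0.01 * rng.normal(size=40)
        sel = uve_select(X, y, n_components=2, seed=0)
        assert 2 not in sel.selected_band_indices

    def test_refit_uses_only_selected_bands(self, rng):
        """Coefficient support of a refit on the subset stays inside it."""
        X, y = informative_data(rng, n=100, p=20, informative=(2, 9))
        sel = uve_select(X, y, n_components=4, seed=0)
        idx = sel.selected_band_indices
        model = PLSRModel(3).fit(X[:, idx], y)
        coef = np.zeros(20)
        coef[idx] = model.coef_.ravel()
        assert np.all(coef[np.setdiff1d(np.arange(20), idx)] == 0)
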