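"""Classical calibration baselines: PLSR, epsilon-SVR, and an RBF network.

All three expose the same ``fit(X, Y) -> self`` / ``predict(X) -> Y_hat``
contract so the evaluation code is model-agnostic.  Targets are standardized
independently per analyte inside each model and inverse-transformed at
prediction time.  Every stochastic component is seeded, so refitting with the
same seed is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .preprocessing import StandardizeStats, standardize

__all__ = ["PLSRModel", "SVMRModel", "RBFNNModel", "select_pls_components"]


def _as_2d_targets(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y.reshape(len(Y), -1)


class PLSRModel:
    """Partial least squares regression (NIPALS), multi-target.

    ``n_components`` is capped at ``min(n_samples - 1, n_bands, rank)`` with a
    warning when the request exceeds it.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = int(n_components)
        self._pls: PLSRegression | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSRModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = _as_2d_targets(Y)
        cap = min(X.shape[0] - 1, X.shape[1], int(np.linalg.matrix_rank(X - X.mean(0))))
        cap = max(cap, 1)
        n_comp = self.n_components
        if n_comp > cap:
            warnings.warn(
                f"n_components={n_comp} exceeds usable rank {cap}; capped",
                stacklevel=2,
            )
            n_comp = cap
        self.n_components_ = n_comp
        self._pls = PLSRegression(n_components=n_comp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns near-singular y residuals
            self._pls.fit(X, Y)
        self._single_target = Y.shape[1] == 1
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._pls is None:
            raise RuntimeError("model is not fitted")
        pred = self._pls.predict(np.atleast_2d(np.asarray(X, dtype=float)))
        return pred.ravel() if self._single_target and pred.ndim > 1 else pred

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients, shape (targets, bands)."""
        if self._pls is None:
            raise RuntimeError("model is not fitted")
        return np.atleast_2d(self._pls.coef_)

    @property
    def intercept_(self) -> np.ndarray:
        if self._pls is None:
            raise RuntimeError("model is not fitted")
        return np.atleast_1d(self._pls.intercept_)


def select_pls_components(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int = 15,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Latent-variable count minimizing pooled k-fold RMSECV over 1..max."""
    from .evaluation import cross_validate

    X = np.atleast_2d(np.asarray(X, dtype=float))
    hi = min(max_components, X.shape[0] - 1 - X.shape[0] // folds, X.shape[1])
    hi = max(hi, 1)
    best_k, best_rmse = 1, np.inf
    for k in range(1, hi + 1):
        rmsecv, _ = cross_validate(lambda k=k: PLSRModel(k), X, Y, folds=folds, seed=seed)
        score = float(np.mean(rmsecv))
        if score < best_rmse - 1e-12:
            best_k, best_rmse = k, score
    return best_k


class SVMRModel:
    """Epsilon-insensitive support vector regression with an RBF kernel.

    One independent SVR per target; targets are z-scored internally.  When
    hyperparameters are not given they are tuned by seeded 5-fold grid search
    over log-spaced C, gamma and epsilon.
    """

    DEFAULT_GRID = {
        "C": np.logspace(-1, 3, 5),
        "gamma": np.logspace(-4, 0, 5),
        "epsilon": np.logspace(-3, -1, 3),
    }

    def __init__(
        self,
        C: float | None = 10.0,
        gamma: float | str | None = "scale",
        epsilon: float | None = 0.01,
        tune: bool = False,
        folds: int = 5,
        seed: int = 0,
    ):
        self.C, self.gamma, self.epsilon = C, gamma, epsilon
        self.tune = tune
        self.folds = folds
        self.seed = seed
        self._models: list[SVR] = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SVMRModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = _as_2d_targets(Y)
        self._single_target = Y.shape[1] == 1
        _, self._y_stats = standardize(Y)
        Z = self._y_stats.transform(Y)
        self._models = []
        for k in range(Z.shape[1]):
            if self.tune:
                cv = KFold(self.folds, shuffle=True, random_state=self.seed)
                search = GridSearchCV(SVR(kernel="rbf"), self.DEFAULT_GRID, cv=cv,
                                      scoring="neg_root_mean_squared_error")
                search.fit(X, Z[:, k])
                model = search.best_estimator_
            else:
                model = SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.epsilon)
                model.fit(X, Z[:, k])
            self._models.append(model)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._models:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.column_stack([m.predict(X) for m in self._models])
        Y = self._y_stats.inverse(Z)
        return Y.ravel() if self._single_target else Y


class RBFNNModel:
    """Three-layer radial basis function network.

    Hidden units are Gaussians of the Euclidean distance to learned centers;
    centers come from seeded k-means, widths from the mean distance to the 2
    nearest other centers, and output weights from ridge-regularized least
    squares on the Gaussian design matrix (with a bias column).
    """

    WIDTH_FLOOR = 1e-8

    def __init__(self, n_centers: int = 20, ridge: float = 1e-8, seed: int = 0,
                 width_rule: str = "mean_2nn", centers: np.ndarray | None = None):
        self.n_centers = int(n_centers)
        self.ridge = float(ridge)
        self.seed = seed
        self.width_rule = width_rule
        self._fixed_centers = centers

    def _widths(self, centers: np.ndarray) -> np.ndarray:
        if len(centers) == 1:
            return np.array([1.0])
        d = cdist(centers, centers)
        np.fill_diagonal(d, np.inf)
        k = min(2, len(centers) - 1)
        nearest = np.sort(d, axis=1)[:, :k]
        return np.maximum(nearest.mean(axis=1), self.WIDTH_FLOOR)

    def _design(self, X: np.ndarray) -> np.ndarray:
        d = cdist(X, self.centers_)
        G = np.exp(-(d ** 2) / (2.0 * self.widths_ ** 2))
        return np.column_stack([G, np.ones(len(X))])

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RBFNNModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = _as_2d_targets(Y)
        self._single_target = Y.shape[1] == 1
        if self._fixed_centers is not None:
            self.centers_ = np.atleast_2d(np.asarray(self._fixed_centers, dtype=float))
        else:
            m = min(self.n_centers, X.shape[0])
            if m == X.shape[0]:
                self.centers_ = X.copy()
            else:
                km = KMeans(n_clusters=m, random_state=self.seed, n_init=10)
                km.fit(X)
                self.centers_ = km.cluster_centers_
        self.widths_ = self._widths(self.centers_)
        _, self._y_stats = standardize(Y) if len(Y) > 1 else (None, StandardizeStats(
            mean=Y.mean(axis=0), scale=np.ones(Y.shape[1])))
        Z = self._y_stats.transform(Y)
        G = self._design(X)
        # ridge-regularized normal equations (bias column unpenalized would be
        # fussier than it is worth at these ridge levels)
        A = G.T @ G + self.ridge * np.eye(G.shape[1])
        self.weights_ = np.linalg.solve(A, G.T @ Z)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._design(X) @ self.weights_
        Y = self._y_stats.inverse(Z)
        return Y.ravel() if self._single_target else Y
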