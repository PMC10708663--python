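"""Sample-set partitioning and the calibration-transfer metric suite.

Metrics follow the conventions of multivariate calibration in NIR/HSI
spectroscopy:

* RMSE on the calibration set (RMSEC), under cross-validation (RMSECV) and on
  the independent test set (RMSEP): ``sqrt(mean((c_hat - c)^2))``.
* Coefficient of determination ``R^2 = 1 - SSres / SStot`` with
  ``SStot = sum((c - c_bar)^2)`` over the *measured* values.
* RPD (residual prediction deviation): sample sd of calibration reference
  values divided by RMSEP, with the conventional interpretation bands
  (<1.5 limited; 1.5-2.0 coarse high/low discrimination; 2.0-2.5 approximate;
  2.5-3.0 good; >3 excellent).
* RER (relative error range): calibration reference range divided by RMSEP.

Partitioning uses the Kennard-Stone max-min-distance algorithm at a default
4:1 calibration:test ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationPair",
    "MetricsReport",
    "SplitResult",
    "kennard_stone_split",
    "rmse",
    "r_squared",
    "rpd",
    "rpd_category",
    "rer",
    "pearson_matrix",
    "cross_validate",
]


@dataclass(frozen=True)
class EvaluationPair:
    """Measured values ``c`` and model estimates ``c_hat`` for one analyte."""

    c: np.ndarray
    c_hat: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float).ravel()
        c_hat = np.asarray(self.c_hat, dtype=float).ravel()
        if c.shape != c_hat.shape:
            raise ValueError("measured and estimated vectors differ in length")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "c_hat", c_hat)

    @property
    def n(self) -> int:
        return self.c.size

    @property
    def c_bar(self) -> float:
        return float(self.c.mean())


def rmse(pair: EvaluationPair) -> float:
    """Root mean square error, ``sqrt(sum((c_hat - c)^2) / n)``."""
    if pair.n < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((pair.c_hat - pair.c) ** 2)))


def r_squared(pair: EvaluationPair) -> float:
    """Coefficient of determination, ``1 - SSres / SStot`` (<= 1)."""
    if pair.n < 2:
        raise ValueError("need >= 2 samples for R^2")
    ss_tot = float(np.sum((pair.c - pair.c_bar) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: measured values have zero variance")
    ss_res = float(np.sum((pair.c_hat - pair.c) ** 2))
    return 1.0 - ss_res / ss_tot


def rpd(calibration_refs: np.ndarray, rmsep: float) -> float:
    """Residual prediction deviation: sd(calibration refs, n-1) / RMSEP."""
    refs = np.asarray(calibration_refs, dtype=float).ravel()
    if refs.size < 2:
        raise ValueError("need >= 2 calibration reference values")
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive for RPD")
    return float(refs.std(ddof=1) / rmsep)


_RPD_BANDS = (
    (1.5, "limited utility (<1.5)"),
    (2.0, "coarse high/low discrimination (1.5-2.0)"),
    (2.5, "approximate prediction (2.0-2.5)"),
    (3.0, "good prediction (2.5-3.0)"),
)


def rpd_category(value: float) -> str:
    """Conventional qualitative band for an RPD value."""
    for upper, label in _RPD_BANDS:
        if value < upper:
            return label
    return "excellent (>3)"


def rer(y_max: float, y_min: float, rmsep: float) -> float:
    """Relative error range, ``(Ymax - Ymin) / RMSEP`` over the calibration
    reference extrema."""
    if rmsep == 0:
        raise ValueError("RMSEP must be nonzero for RER")
    return float((y_max - y_min) / rmsep)


def pearson_matrix(concentrations: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix across analytes (columns)."""
    C = np.asarray(concentrations, dtype=float)
    if C.ndim != 2 or C.shape[0] < 3:
        raise ValueError("need a samples x analytes matrix with >= 3 samples")
    if np.any(C.std(axis=0) == 0):
        raise ValueError("zero-variance analyte: correlation undefined")
    return np.corrcoef(C, rowvar=False)


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive calibration/test index lists."""

    calibration_ids: np.ndarray
    test_ids: np.ndarray
    ratio: float
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_ids, dtype=int)
        test = np.asarray(self.test_ids, dtype=int)
        if np.intersect1d(cal, test).size:
            raise ValueError("calibration and test sets overlap")
        object.__setattr__(self, "calibration_ids", cal)
        object.__setattr__(self, "test_ids", test)

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(i), "calibration") for i in self.calibration_ids] + [
            (int(i), "test") for i in self.test_ids
        ]
        return pd.DataFrame(rows, columns=["sample_index", "subset"])


def kennard_stone_split(features: np.ndarray, ratio: float = 4 / 5) -> SplitResult:
    """Kennard-Stone max-min partition into calibration and test subsets.

    Seeds with the two samples at maximal Euclidean distance, then repeatedly
    adds the sample whose minimum distance to the selected set is largest,
    until ``floor(n * ratio)`` samples are selected (``ratio`` is the
    calibration fraction; the default 4/5 is the usual 4:1 split).  All ties
    break to the lowest sample index, so the procedure is deterministic.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.ndim != 2:
        raise ValueError("features must be a samples x dims matrix")
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 samples for a meaningful split, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n_cal = int(np.floor(n * ratio))

    # pairwise distances; argmax with lowest-index tie-break via flat order
    from scipy.spatial.distance import cdist

    dist = cdist(X, X)
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False

    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    while len(selected) < n_cal:
        masked = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(masked))  # np.argmax takes the first (lowest) index
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, dist[nxt])

    test = np.flatnonzero(remaining)
    return SplitResult(
        calibration_ids=np.array(selected, dtype=int),
        test_ids=test,
        ratio=ratio,
    )


def cross_validate(
    model_factory,
    X: np.ndarray,
    Y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-fold cross-validation on the calibration set.

    ``model_factory()`` must return an object with ``fit(X, Y)`` and
    ``predict(X)``.  Out-of-fold predictions are pooled and RMSECV / Rcv^2 are
    computed once on the pooled vectors, per target column.

    Returns ``(rmsecv, rcv2)`` arrays of length ``n_targets``.
    """
    from sklearn.model_selection import KFold

    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    Y2 = Y.reshape(len(X), -1)
    n = X.shape[0]
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, n={n}], got {folds}")
    pooled = np.empty_like(Y2)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        model = model_factory()
        model.fit(X[train_idx], Y2[train_idx].squeeze() if Y.ndim == 1 else Y2[train_idx])
        pred = np.asarray(model.predict(X[test_idx]), dtype=float).reshape(len(test_idx), -1)
        pooled[test_idx] = pred
    rmsecv = np.array(
        [rmse(EvaluationPair(Y2[:, k], pooled[:, k])) for k in range(Y2.shape[1])]
    )
    rcv2 = np.array(
        [r_squared(EvaluationPair(Y2[:, k], pooled[:, k])) for k in range(Y2.shape[1])]
    )
    return rmsecv, rcv2


@dataclass
class MetricsReport:
    """Per-analyte metric table in the usual calibration-report layout."""

    analyte_names: tuple[str, ...]
    rmsec: np.ndarray
    rc2: np.ndarray
    rmsep: np.ndarray
    rp2: np.ndarray
    rpd: np.ndarray
    rer: np.ndarray
    rpd_categories: tuple[str, ...]
    rmsecv: np.ndarray | None = None
    rcv2: np.ndarray | None = None

    @classmethod
    def from_predictions(
        cls,
        analyte_names,
        y_cal: np.ndarray,
        yhat_cal: np.ndarray,
        y_test: np.ndarray,
        yhat_test: np.ndarray,
        rmsecv: np.ndarray | None = None,
        rcv2: np.ndarray | None = None,
    ) -> "MetricsReport":
        y_cal = np.asarray(y_cal, float).reshape(len(y_cal), -1)
        yhat_cal = np.asarray(yhat_cal, float).reshape(len(yhat_cal), -1)
        y_test = np.asarray(y_test, float).reshape(len(y_test), -1)
        yhat_test = np.asarray(yhat_test, float).reshape(len(yhat_test), -1)
        k = y_cal.shape[1]
        rmsec = np.array([rmse(EvaluationPair(y_cal[:, a], yhat_cal[:, a])) for a in range(k)])
        rc2 = np.array([r_squared(EvaluationPair(y_cal[:, a], yhat_cal[:, a])) for a in range(k)])
        rmsep = np.array([rmse(EvaluationPair(y_test[:, a], yhat_test[:, a])) for a in range(k)])
        rp2 = np.array([r_squared(EvaluationPair(y_test[:, a], yhat_test[:, a])) for a in range(k)])
        rpds = np.array([rpd(y_cal[:, a], rmsep[a]) if rmsep[a] > 0 else np.inf for a in range(k)])
        rers = np.array(
            [
                rer(y_cal[:, a].max(), y_cal[:, a].min(), rmsep[a]) if rmsep[a] > 0 else np.inf
                for a in range(k)
            ]
        )
        cats = tuple(rpd_category(v) for v in rpds)
        return cls(
            analyte_names=tuple(analyte_names),
            rmsec=rmsec, rc2=rc2, rmsep=rmsep, rp2=rp2,
            rpd=rpds, rer=rers, rpd_categories=cats,
            rmsecv=rmsecv, rcv2=rcv2,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "Rc2": self.rc2,
            "RMSEC": self.rmsec,
            "Rp2": self.rp2,
            "RMSEP": self.rmsep,
            "RER": self.rer,
            "RPD": self.rpd,
            "RPD_category": list(self.rpd_categories),
        }
        if self.rmsecv is not None:
            cols["RMSECV"] = self.rmsecv
        if self.rcv2 is not None:
            cols["Rcv2"] = self.rcv2
        return pd.DataFrame(cols, index=list(self.analyte_names))

    def to_json_dict(self) -> dict:
        frame = self.to_frame()
        return {name: frame.loc[name].to_dict() for name in frame.index}
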