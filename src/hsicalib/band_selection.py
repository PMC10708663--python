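"""Wavelength-subset selection: CARS, SPA, and UVE.

Three classical chemometric variable selectors, all built on the same PLS
engine as the calibration baselines so coefficient conventions agree:

* **CARS** (competitive adaptive reweighted sampling): N Monte-Carlo runs; in
  run i a PLS model is fitted on a random sample subset, variables are ranked
  by |regression coefficient|, an exponentially decreasing fraction
  ``r_i = a * exp(-k * i)`` of them is enforced (r_1 = 1 down to r_N = 2/p),
  then adaptive reweighted sampling draws among the survivors.  The subset
  with minimal cross-validated RMSE wins.
* **SPA** (successive projections algorithm): forward selection that
  repeatedly appends the column with maximal norm after projection onto the
  orthogonal complement of the chosen columns, minimizing collinearity.
* **UVE** (uninformative variable elimination): appends artificial noise
  columns, computes leave-one-out PLS coefficient stability
  ``c_j = mean(b_j) / sd(b_j)``, and eliminates real variables whose |c_j|
  does not exceed the largest noise stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .baseline_models import PLSRModel
from .evaluation import EvaluationPair, cross_validate, rmse

__all__ = ["SelectionResult", "cars_select", "spa_select", "uve_select", "cars_retention_schedule"]


@dataclass
class SelectionResult:
    """Outcome of a band-selection run."""

    selected_band_indices: np.ndarray
    method: str
    seed: int | None = None
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_band_indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selected band indices must be unique")
        self.selected_band_indices = idx

    def to_json_dict(self, wavelengths_nm: np.ndarray | None = None) -> dict:
        payload = {
            "method": self.method,
            "seed": self.seed,
            "selected_band_indices": [int(i) for i in self.selected_band_indices],
            "history": self.history,
        }
        if wavelengths_nm is not None:
            payload["selected_wavelengths_nm"] = [
                float(wavelengths_nm[i]) for i in self.selected_band_indices
            ]
        return payload


def cars_retention_schedule(n_runs: int, n_bands: int) -> np.ndarray:
    """Exponentially decreasing fraction of variables kept per CARS run.

    ``r_i = a * exp(-k * i)`` with the endpoint conditions ``r_1 = 1`` and
    ``r_N = 2 / p``, hence ``k = ln(p/2) / (N - 1)`` and ``a = e^k``.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    if n_bands < 2:
        raise ValueError("need n_bands >= 2")
    k = np.log(n_bands / 2.0) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def _pls_abs_coefs(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    model = PLSRModel(n_components=max(n_comp, 1)).fit(X, y)
    return np.abs(model.coef_).ravel()


def _subset_rmsecv(X: np.ndarray, y: np.ndarray, idx: np.ndarray,
                   n_components: int, cv_folds: int, seed: int) -> float:
    n_comp = max(1, min(n_components, len(idx), X.shape[0] - 1 - X.shape[0] // cv_folds))
    rmsecv, _ = cross_validate(
        lambda: PLSRModel(n_comp), X[:, idx], y, folds=cv_folds, seed=seed
    )
    return float(rmsecv.mean())


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
    n_components: int = 10,
    sampling_ratio: float = 0.8,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the band axis."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    if p < 2:
        raise ValueError("need at least 2 bands")
    rng = np.random.default_rng(seed)
    ratios = cars_retention_schedule(n_runs, p)

    survivors = np.arange(p)
    best_idx, best_rmse = survivors.copy(), np.inf
    history: list[dict] = []
    for i in range(n_runs):
        m = max(2, int(round(sampling_ratio * n)))
        rows = rng.choice(n, size=m, replace=False)
        coefs = np.zeros(p)
        coefs[survivors] = _pls_abs_coefs(X[np.ix_(rows, survivors)], y[rows], n_components)

        # enforced exponential decrease: keep the top r_i * p variables
        n_keep = max(2, int(round(ratios[i] * p)))
        n_keep = min(n_keep, len(survivors))
        order = np.lexsort((survivors, -coefs[survivors]))  # ties -> lower index
        enforced = survivors[order[:n_keep]]

        # adaptive reweighted sampling among the enforced survivors
        w = coefs[enforced]
        if w.sum() > 0 and len(enforced) > 2:
            picks = rng.choice(enforced, size=len(enforced), replace=True, p=w / w.sum())
            sampled = np.unique(picks)
            if len(sampled) >= 2:
                enforced = sampled
        survivors = np.sort(enforced)

        score = _subset_rmsecv(X, y, survivors, n_components, cv_folds, seed)
        history.append(
            {"run": i + 1, "kept_fraction": len(survivors) / p,
             "rmsecv": score, "n_kept": int(len(survivors))}
        )
        if score < best_rmse:
            best_rmse, best_idx = score, survivors.copy()
    return SelectionResult(best_idx, method="CARS", seed=seed, history=history)


def spa_select(
    X: np.ndarray,
    k_max: int,
    start: int | str = 0,
    y: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Successive projections algorithm.

    From the ``start`` column (or the best over all starts when
    ``start="scan"``, scored by the final chain's validation RMSE — requires
    ``y``), repeatedly appends the column of maximal residual norm after
    projecting out the selected columns.  When ``y`` is given the final subset
    size is chosen by cross-validated RMSE over 1..k_max chain prefixes;
    otherwise the full chain of length ``k_max`` is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if k_max > min(n - 1, p) and y is not None:
        raise ValueError(f"k_max must be <= min(samples - 1, bands) = {min(n - 1, p)}")
    k_max = min(k_max, p)

    def chain(s: int) -> list[int]:
        selected = [s]
        R = X.copy()
        v = X[:, s]
        for _ in range(1, k_max):
            denom = float(v @ v)
            if denom <= 1e-300:
                break
            R = R - np.outer(v, (v @ R) / denom)
            norms = np.linalg.norm(R, axis=0)
            norms[selected] = -1.0
            if norms.max() <= 1e-12:
                warnings.warn("SPA chain stopped early: remaining columns are "
                              "in the span of the selected set", stacklevel=3)
                break
            nxt = int(np.argmax(norms))  # first max -> lowest index on ties
            selected.append(nxt)
            v = R[:, nxt]
        return selected

    starts = range(p) if start == "scan" else [int(start)]
    best: tuple[float, list[int]] | None = None
    for s in starts:
        sel = chain(s)
        if y is None:
            score = 0.0
            prefix = sel
        else:
            score, prefix = _best_prefix(X, np.asarray(y, float).ravel(), sel, cv_folds, seed)
        if best is None or score < best[0]:
            best = (score, prefix)
    assert best is not None
    return SelectionResult(np.array(best[1], dtype=int), method="SPA", seed=seed,
                           history=[{"score": best[0]}])


def _best_prefix(X, y, sel: list[int], cv_folds: int, seed: int) -> tuple[float, list[int]]:
    best_score, best_len = np.inf, 1
    for k in range(1, len(sel) + 1):
        idx = np.array(sel[:k])
        score = _subset_rmsecv(X, y, idx, n_components=min(k, 10),
                               cv_folds=min(cv_folds, len(y)), seed=seed)
        if score < best_score - 1e-12:
            best_score, best_len = score, k
    return best_score, sel[:best_len]


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    seed: int = 0,
    noise_amplitude: float = 1e-10,
) -> SelectionResult:
    """Uninformative variable elimination with appended noise columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < n_components + 2:
        raise ValueError("need samples >= n_components + 2")
    rng = np.random.default_rng(seed)
    scale = noise_amplitude * max(np.abs(X).max(), 1.0)
    noise = rng.uniform(0.0, scale, size=(n, p))
    Xa = np.hstack([X, noise])

    # leave-one-out PLS coefficient vectors
    B = np.empty((n, 2 * p))
    for i in range(n):
        keep = np.arange(n) != i
        model = PLSRModel(min(n_components, n - 2)).fit(Xa[keep], y[keep])
        B[i] = model.coef_.ravel()
    mean_b = B.mean(axis=0)
    sd_b = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd_b > 0, mean_b / sd_b, 0.0)
    if np.any(sd_b == 0):
        warnings.warn("zero-variance PLS coefficient(s): stability set to 0",
                      stacklevel=2)
    cutoff = np.abs(c[p:]).max()
    kept = np.flatnonzero(np.abs(c[:p]) > cutoff)
    history = [{"cutoff": float(cutoff),
                "stability": [float(v) for v in c[:p]]}]
    return SelectionResult(kept, method="UVE", seed=seed, history=history)
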