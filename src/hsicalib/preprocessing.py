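"""Spectral preprocessing operators for the classical calibration workflow.

Savitzky-Golay smoothing/derivatives and column standardization.  The default
classical pipeline applies *no* preprocessing — on this kind of reflectance
data raw spectra routinely calibrate at least as well as smoothed or
differentiated ones — so every step here is opt-in via :class:`PreprocSpec`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .hsi_core import to_absorbance

__all__ = ["PreprocSpec", "StandardizeStats", "sg_filter", "standardize", "apply_spec"]

SCALE_FLOOR = 1e-12

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 2


def _check_sg_params(window: int, polyorder: int, deriv_order: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
    if deriv_order > polyorder:
        raise ValueError(
            f"deriv_order ({deriv_order}) must be <= polyorder ({polyorder})"
        )


def sg_filter(
    spectrum: np.ndarray,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    deriv_order: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay local-polynomial filter along the last axis.

    Length-preserving; edges handled by polynomial extrapolation (``interp``
    mode).  ``delta`` is the band spacing used to scale derivatives.
    """
    _check_sg_params(window, polyorder, deriv_order)
    x = np.asarray(spectrum, dtype=float)
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=delta, axis=-1, mode="interp",
    )


@dataclass(frozen=True)
class StandardizeStats:
    """Fitted column means and scales (sample sd, n-1 convention)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.scale

    def inverse(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=float) * self.scale + self.mean


def standardize(
    matrix: np.ndarray, stats: StandardizeStats | None = None
) -> tuple[np.ndarray, StandardizeStats]:
    """Column-wise zero-mean unit-variance scaling (samples x bands).

    When ``stats`` is given it is applied as-is; otherwise it is fitted with
    the sample (n-1) standard deviation.  Zero-variance columns get a floored
    scale and a warning (they standardize to zero).
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if stats is None:
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples to fit standardization stats")
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        if np.any(scale <= SCALE_FLOOR):
            warnings.warn(
                f"{int(np.sum(scale <= SCALE_FLOOR))} zero-variance column(s); "
                "scale floored",
                stacklevel=2,
            )
            scale = np.maximum(scale, SCALE_FLOOR)
        stats = StandardizeStats(mean=mean, scale=scale)
    return stats.transform(X), stats


@dataclass
class PreprocSpec:
    """Ordered preprocessing chain applied to a samples x bands matrix.

    Steps (dicts with a ``name`` key):
      ``{"name": "sg_smooth", "window": 11, "polyorder": 2}``
      ``{"name": "sg_derivative", "window": 11, "polyorder": 2, "deriv_order": 1}``
      ``{"name": "standardize"}``
      ``{"name": "absorbance"}``  — log10(1/R) on reflectance rows
    """

    steps: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for step in self.steps:
            name = step.get("name")
            if name in ("sg_smooth", "sg_derivative"):
                _check_sg_params(
                    step.get("window", DEFAULT_SG_WINDOW),
                    step.get("polyorder", DEFAULT_SG_POLYORDER),
                    step.get("deriv_order", 1 if name == "sg_derivative" else 0),
                )
            elif name not in ("standardize", "absorbance"):
                raise ValueError(f"unknown preprocessing step {name!r}")

    def to_dict(self) -> dict:
        return {"steps": [dict(s) for s in self.steps]}

    @classmethod
    def from_dict(cls, payload: dict) -> "PreprocSpec":
        return cls(steps=list(payload.get("steps", [])))


def apply_spec(
    matrix: np.ndarray,
    spec: PreprocSpec,
    fitted: list[StandardizeStats] | None = None,
) -> tuple[np.ndarray, list[StandardizeStats]]:
    """Run a :class:`PreprocSpec` chain; returns the matrix and the fitted
    standardization stats (reusable on new data via ``fitted=``)."""
    from .hsi_core import ABSORBANCE_REFLECTANCE_FLOOR

    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    out_stats: list[StandardizeStats] = []
    fit_iter = iter(fitted) if fitted is not None else None
    for step in spec.steps:
        name = step["name"]
        if name == "sg_smooth":
            X = sg_filter(
                X, step.get("window", DEFAULT_SG_WINDOW),
                step.get("polyorder", DEFAULT_SG_POLYORDER), 0,
            )
        elif name == "sg_derivative":
            X = sg_filter(
                X, step.get("window", DEFAULT_SG_WINDOW),
                step.get("polyorder", DEFAULT_SG_POLYORDER),
                step.get("deriv_order", 1), step.get("delta", 1.0),
            )
        elif name == "absorbance":
            X = np.log10(1.0 / np.maximum(X, ABSORBANCE_REFLECTANCE_FLOOR))
        elif name == "standardize":
            stats = next(fit_iter) if fit_iter is not None else None
            X, stats = standardize(X, stats)
            out_stats.append(stats)
    return X, out_stats
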