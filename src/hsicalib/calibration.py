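"""Model/Results interface tying the whole calibration workflow together.

:class:`CalibrationModel` is constructed from sample records (or a plain
feature matrix plus targets), partitions them with Kennard-Stone, fits the
chosen regressor on the calibration subset, and returns a
:class:`CalibrationResults` carrying per-analyte error metrics, the split, the
predictions, and a ``summary()`` table in the conventional layout
(Rc2/RMSEC/Rp2/RMSEP/RER/RPD per analyte).

Estimators: ``"plsr"``, ``"svmr"``, ``"rbfnn"`` operate on the per-sample
mean spectra; ``"se_resnet"`` trains the deep model on image patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_selection import SelectionResult
from .baseline_models import PLSRModel, RBFNNModel, SVMRModel, select_pls_components
from .evaluation import (
    MetricsReport, SplitResult, cross_validate, kennard_stone_split,
)
from .preprocessing import PreprocSpec, apply_spec
from .segmentation import ANALYTE_NAMES, SampleRecord

__all__ = ["CalibrationModel", "CalibrationResults"]


class CalibrationModel:
    """A spectra-to-concentrations calibration experiment.

    Parameters
    ----------
    X : samples x bands matrix of mean spectra.
    Y : samples x analytes reference concentrations.
    records : alternative to ``X``/``Y``; list of :class:`SampleRecord`
        (required for the deep model, which consumes patches).
    estimator : one of ``plsr``, ``svmr``, ``rbfnn``, ``se_resnet``.
    preprocessing : optional :class:`PreprocSpec` applied to the spectra
        before splitting/fitting (classical estimators only).
    band_subset : optional band-index array or :class:`SelectionResult`
        restricting the classical estimators to selected wavelengths.
    split_ratio : calibration fraction for the Kennard-Stone split.
    cv_folds : folds for cross-validation metrics; ``None`` skips RMSECV/Rcv2.
    """

    def __init__(
        self,
        X: np.ndarray | None = None,
        Y: np.ndarray | None = None,
        records: list[SampleRecord] | None = None,
        estimator: str = "plsr",
        estimator_kwargs: dict | None = None,
        preprocessing: PreprocSpec | None = None,
        band_subset=None,
        analyte_names: tuple[str, ...] | None = None,
        split_ratio: float = 4 / 5,
        cv_folds: int | None = None,
        seed: int = 0,
    ):
        if records is not None:
            self.records = list(records)
            X = np.stack([r.mean_spectrum for r in self.records])
            Y = np.stack([r.concentrations for r in self.records])
            analyte_names = analyte_names or self.records[0].analyte_names
        else:
            if X is None or Y is None:
                raise ValueError("provide either records or both X and Y")
            self.records = None
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Y = np.asarray(Y, dtype=float).reshape(len(self.X), -1)
        self.analyte_names = tuple(
            analyte_names or ANALYTE_NAMES[: self.Y.shape[1]]
        )
        if estimator not in ("plsr", "svmr", "rbfnn", "se_resnet"):
            raise ValueError(f"unknown estimator {estimator!r}")
        if estimator == "se_resnet" and self.records is None:
            raise ValueError("the deep model needs records with patches")
        self.estimator = estimator
        self.estimator_kwargs = dict(estimator_kwargs or {})
        self.preprocessing = preprocessing
        if isinstance(band_subset, SelectionResult):
            band_subset = band_subset.selected_band_indices
        self.band_subset = None if band_subset is None else np.asarray(band_subset, int)
        self.split_ratio = split_ratio
        self.cv_folds = cv_folds
        self.seed = seed

    @classmethod
    def from_records(cls, records: list[SampleRecord], **kwargs) -> "CalibrationModel":
        return cls(records=records, **kwargs)

    # ------------------------------------------------------------------
    def _features(self) -> tuple[np.ndarray, list]:
        X = self.X
        stats: list = []
        if self.preprocessing is not None:
            X, stats = apply_spec(X, self.preprocessing)
        if self.band_subset is not None:
            X = X[:, self.band_subset]
        return X, stats

    def _make_estimator(self, n_cal: int):
        kw = dict(self.estimator_kwargs)
        if self.estimator == "plsr":
            kw.setdefault("n_components", 10)
            return PLSRModel(**kw)
        if self.estimator == "svmr":
            kw.setdefault("seed", self.seed)
            return SVMRModel(**kw)
        if self.estimator == "rbfnn":
            kw.setdefault("seed", self.seed)
            kw.setdefault("n_centers", max(5, n_cal // 4))
            return RBFNNModel(**kw)
        raise AssertionError

    def fit(self) -> "CalibrationResults":
        feats, _ = self._features()
        split = kennard_stone_split(feats, self.split_ratio)
        cal_idx, test_idx = split.calibration_ids, split.test_ids

        if self.estimator == "se_resnet":
            from .se_resnet import SEResNetRegressor

            reg = SEResNetRegressor(seed=self.seed, **self.estimator_kwargs)
            cal_recs = [self.records[i] for i in cal_idx]
            reg.fit_records(cal_recs)
            yhat_cal = reg.predict_records(cal_recs)
            yhat_test = reg.predict_records([self.records[i] for i in test_idx])
            fitted = reg
            rmsecv = rcv2 = None
        else:
            est = self._make_estimator(len(cal_idx))
            est.fit(feats[cal_idx], self.Y[cal_idx])
            yhat_cal = np.asarray(est.predict(feats[cal_idx])).reshape(len(cal_idx), -1)
            yhat_test = np.asarray(est.predict(feats[test_idx])).reshape(len(test_idx), -1)
            fitted = est
            rmsecv = rcv2 = None
            if self.cv_folds:
                rmsecv, rcv2 = cross_validate(
                    lambda: self._make_estimator(len(cal_idx)),
                    feats[cal_idx], self.Y[cal_idx],
                    folds=self.cv_folds, seed=self.seed,
                )

        report = MetricsReport.from_predictions(
            self.analyte_names,
            self.Y[cal_idx], yhat_cal, self.Y[test_idx], yhat_test,
            rmsecv=rmsecv, rcv2=rcv2,
        )
        return CalibrationResults(
            model=self, estimator=fitted, split=split, report=report,
            yhat_cal=yhat_cal, yhat_test=yhat_test,
        )


@dataclass
class CalibrationResults:
    """Fitted-experiment container: estimates, errors, diagnostics."""

    model: CalibrationModel
    estimator: object
    split: SplitResult
    report: MetricsReport
    yhat_cal: np.ndarray
    yhat_test: np.ndarray

    @property
    def rp2(self) -> np.ndarray:
        return self.report.rp2

    @property
    def rmsep(self) -> np.ndarray:
        return self.report.rmsep

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def summary(self) -> str:
        """Human-readable per-analyte metric table."""
        frame = self.to_frame()
        lines = [
            f"Calibration results ({self.model.estimator}, "
            f"{len(self.split.calibration_ids)} calibration / "
            f"{len(self.split.test_ids)} test samples)",
            "=" * 78,
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def predicted_vs_measured(self) -> pd.DataFrame:
        """Long-form test-set table for correlation plots."""
        rows = []
        Yt = self.model.Y[self.split.test_ids]
        for k, name in enumerate(self.model.analyte_names):
            for c, chat in zip(Yt[:, k], self.yhat_test[:, k]):
                rows.append({"analyte": name, "measured": c, "predicted": chat})
        return pd.DataFrame(rows)

    def plot_predictions(self, path: str | None = None):
        """Predicted-vs-measured scatter per analyte (test set)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = self.model.analyte_names
        fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.2))
        axes = np.atleast_1d(axes)
        Yt = self.model.Y[self.split.test_ids]
        for k, (ax, name) in enumerate(zip(axes, names)):
            ax.scatter(Yt[:, k], self.yhat_test[:, k], s=12)
            lo = min(Yt[:, k].min(), self.yhat_test[:, k].min())
            hi = max(Yt[:, k].max(), self.yhat_test[:, k].max())
            ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
            ax.set_title(f"{name}\nRp2={self.report.rp2[k]:.3f}", fontsize=8)
            ax.set_xlabel("measured")
            if k == 0:
                ax.set_ylabel("predicted")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
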