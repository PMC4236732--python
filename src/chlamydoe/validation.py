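"""Predictive validation: k-fold cross-validation and held-out test points.

Cross-validation refits the model spec on each training complement
(recomputing the centering constants on the training rows, exactly as a
fresh fit would) and scores the held-out predictions; both the pooled
errors over all held-out points and the average of per-fold errors are
reported.  Experimental validation scores a published model against new
measured factor combinations (mean absolute and root-mean-square
error, MAE_EV / RMSE_EV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignTable
from .published import PublishedModel
from .regression import ModelSpec, RankDeficientError, ResponseSurfaceModel

__all__ = [
    "ValidationReport",
    "kfold_cv",
    "experimental_validation",
    "load_validation_points",
]


@dataclass
class ValidationReport:
    """Per-point errors and MAE/RMSE summaries for one response.

    ``mode`` is ``"cv"`` or ``"ev"``.  For cv mode, ``mae``/``rmse`` are
    pooled over all held-out predictions, ``mae_fold_avg``/
    ``rmse_fold_avg`` average the per-fold values, and
    ``training_models`` summarizes each training fit.
    """

    response: str
    mode: str
    mae: float
    rmse: float
    abs_errors: np.ndarray
    k: int | None = None
    n_points: int | None = None
    fold_assignment: np.ndarray | None = None
    mae_fold_avg: float | None = None
    rmse_fold_avg: float | None = None
    per_fold: pd.DataFrame | None = None
    training_models: pd.DataFrame | None = None
    skipped_points: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "response": self.response,
            "mode": self.mode,
            "mae": self.mae,
            "rmse": self.rmse,
            "n_points": self.n_points if self.n_points is not None else len(self.abs_errors),
        }
        if self.mode == "cv":
            out.update(
                k=self.k,
                mae_fold_avg=self.mae_fold_avg,
                rmse_fold_avg=self.rmse_fold_avg,
                training=None if self.training_models is None
                else self.training_models.mean(numeric_only=True).to_dict(),
            )
        return out


def _partition(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random assignment of n rows to k near-equal folds."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def kfold_cv(
    design: DesignTable,
    y,
    spec: ModelSpec,
    k: int = 5,
    folds: np.ndarray | None = None,
    seed: int = 0,
) -> ValidationReport:
    """k-fold cross-validation of a model spec on one response.

    Rows with missing ``y`` are dropped before folding.  ``folds`` may
    give an explicit fold label per surviving row; otherwise a seeded
    random near-equal partition is used.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    yv = np.asarray(y, dtype=float)
    keep = ~np.isnan(yv)
    yv = yv[keep]
    data = design.factor_data().loc[keep].reset_index(drop=True)
    n = len(yv)
    if folds is None:
        folds = _partition(n, k, seed)
    else:
        folds = np.asarray(folds)
        if len(folds) != n:
            raise ValueError("explicit fold assignment must match the non-missing rows")
        k = len(np.unique(folds))

    abs_err = np.empty(n)
    fold_rows = []
    train_rows = []
    for label in np.unique(folds):
        test = folds == label
        train = ~test
        try:
            model = ResponseSurfaceModel(
                yv[train], data.loc[train], spec.terms, design.factors,
                response=spec.response,
            )
            res = model.fit()
        except (RankDeficientError, ValueError) as exc:
            raise RuntimeError(f"training fit failed for fold {label}: {exc}") from exc
        pred = res.predict(data.loc[test])
        err = np.abs(yv[test] - pred)
        abs_err[test] = err
        fold_rows.append({
            "fold": label, "n_test": int(test.sum()),
            "mae": float(err.mean()), "rmse": float(np.sqrt((err**2).mean())),
        })
        train_rows.append({
            "fold": label, "r2": res.rsquared, "r2_adj": res.rsquared_adj,
            "mae_f": res.mae, "rmse_f": res.rmse,
        })
    per_fold = pd.DataFrame(fold_rows)
    return ValidationReport(
        response=spec.response,
        mode="cv",
        mae=float(abs_err.mean()),
        rmse=float(np.sqrt((abs_err**2).mean())),
        abs_errors=abs_err,
        k=int(k),
        n_points=n,
        fold_assignment=folds,
        mae_fold_avg=float(per_fold["mae"].mean()),
        rmse_fold_avg=float(per_fold["rmse"].mean()),
        per_fold=per_fold,
        training_models=pd.DataFrame(train_rows),
    )


def experimental_validation(
    model: PublishedModel,
    points: pd.DataFrame,
    measured_col: str | None = None,
) -> ValidationReport:
    """Score a published model against measured validation combinations.

    ``points`` holds one row per combination with factor columns and a
    measured-response column (named like the model's response by
    default).  Rows with a missing measurement are skipped with a
    warning.
    """
    if points.empty:
        raise ValueError("points table is empty")
    col = measured_col or model.response
    if col not in points.columns:
        raise KeyError(f"points table has no measured column {col!r}")
    measured = points[col].to_numpy(float)
    keep = np.isfinite(measured)
    skipped = [int(i) for i in np.nonzero(~keep)[0]]
    if skipped:
        warnings.warn(f"{model.response}: skipping {len(skipped)} points with "
                      "missing measurements")
    sub = points.loc[keep]
    pred = np.asarray(
        model.predict({f: sub[f].to_numpy(float) for f in model.factor_names})
    )
    err = np.abs(sub[col].to_numpy(float) - pred)
    return ValidationReport(
        response=model.response,
        mode="ev",
        mae=float(err.mean()),
        rmse=float(math.sqrt((err**2).mean())),
        abs_errors=err,
        n_points=int(keep.sum()),
        skipped_points=skipped,
    )


def load_validation_points(path=None) -> pd.DataFrame:
    """The packaged experimental-validation combinations (means +/- SD).

    Six combinations carry all six responses; two extra combinations
    were measured for the photosynthetic responses only (missing values
    for the respiratory ones).
    """
    if path is None:
        with resources.files("chlamydoe.data").joinpath("validation_points.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)
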