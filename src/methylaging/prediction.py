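"""Age prediction from selected markers and external linear clocks.

A random-forest regressor (100 trees, unlimited depth, all features per
split, squared-error criterion — classic defaults, no tuning) is evaluated
by shuffled 5-fold cross-validation: per fold, train on 80% of samples and
predict the held-out 20%.  Missing features are imputed with the training
fold's per-marker median only, so no information leaks from validation
samples.  Linear epigenetic clocks (a coefficient per marker plus an
intercept, optionally followed by an inverse age transform) can be applied
to the same matrix for comparison.  The signed error in the oldest age
decile quantifies the systematic underprediction that linear clocks show
when methylation trajectories saturate with age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClockModel",
    "RandomForestAgePredictor",
    "rf_cv",
    "apply_linear_clock",
    "signed_error_by_age",
]

_RF_DEFAULTS = dict(
    n_estimators=100,
    max_depth=None,
    bootstrap=True,
    criterion="squared_error",
    max_features=1.0,  # all features considered at every split
)


@dataclass
class ClockModel:
    """Linear age clock: intercept + sum(coef * beta), optional inverse transform.

    ``transform`` may be ``None`` (identity) or ``{"type": "horvath",
    "adult_age": 20}``: the piecewise log-linear age transform used by
    multi-tissue clocks, inverted here to map the linear predictor back to
    years.
    """

    intercept: float
    coefficients: pd.Series
    transform: dict | None = None

    def inverse_transform(self, linear_pred: np.ndarray) -> np.ndarray:
        if self.transform is None:
            return linear_pred
        if self.transform.get("type") == "horvath":
            adult = float(self.transform.get("adult_age", 20))
            return np.where(
                linear_pred < 0,
                (1 + adult) * np.exp(linear_pred) - 1,
                (1 + adult) * linear_pred + adult,
            )
        raise ValueError(f"unknown clock transform {self.transform!r}")


class RandomForestAgePredictor(BaseEstimator, RegressorMixin):
    """Random forest over marker betas with leakage-safe median imputation.

    ``fit(X, y)`` learns per-marker medians on the training data and an
    untuned random forest; ``predict`` imputes with the stored training
    medians before predicting.
    """

    def __init__(self, seed: int = 0, **rf_params):
        self.seed = seed
        self.rf_params = rf_params

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.impute_values_ = np.nanmedian(X, axis=0)
        params = {**_RF_DEFAULTS, **self.rf_params}
        self.forest_ = RandomForestRegressor(random_state=self.seed, **params)
        self.forest_.fit(self._impute(X), y)
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = self.impute_values_[nan_c]
        return X

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._impute(np.asarray(X, dtype=float)))


def rf_cv(
    features: pd.DataFrame,
    ages,
    folds: int = 5,
    seed: int = 0,
    rf_params: dict | None = None,
) -> dict:
    """Shuffled k-fold cross-validated random-forest age prediction.

    ``features`` is samples x markers.  Returns a report dict with per-fold
    mean absolute error (years) and Pearson r, their mean and SD across
    folds, and the full out-of-fold prediction table.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    if len(y) < folds:
        raise ValueError("need at least as many samples as folds")
    sample_ids = (
        list(features.index) if isinstance(features, pd.DataFrame) else [str(i) for i in range(len(y))]
    )
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mae, fold_r = [], []
    rows = []
    constant_age = np.std(y) == 0
    for fold, (train, test) in enumerate(kf.split(X)):
        model = RandomForestAgePredictor(seed=seed, **(rf_params or {}))
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        fold_mae.append(float(np.mean(np.abs(pred - y[test]))))
        if constant_age or np.std(y[test]) == 0 or np.std(pred) == 0:
            fold_r.append(float("nan"))
        else:
            fold_r.append(float(stats.pearsonr(pred, y[test])[0]))
        for j, p in zip(test, pred):
            rows.append((sample_ids[j], float(y[j]), float(p), fold))
    predictions = pd.DataFrame(rows, columns=["sample_id", "age", "predicted_age", "fold"])
    report = {
        "folds": folds,
        "fold_mae": fold_mae,
        "mae_mean": float(np.mean(fold_mae)),
        "mae_sd": float(np.std(fold_mae, ddof=1)) if folds > 1 else 0.0,
        "fold_pearson": fold_r,
        "pearson_mean": float(np.nanmean(fold_r)) if not all(np.isnan(fold_r)) else None,
        "pearson_sd": float(np.nanstd(fold_r, ddof=1)) if folds > 1 and not all(np.isnan(fold_r)) else None,
        "predictions": predictions,
    }
    if constant_age:
        report["warning"] = "constant age vector; Pearson correlation undefined"
    return report


def apply_linear_clock(
    clock: ClockModel, matrix: pd.DataFrame, drop_missing: bool = False
) -> pd.Series:
    """Predicted age per sample from a linear clock on a probes x samples matrix.

    Every clock marker must be present unless ``drop_missing``, in which case
    absent markers are skipped (their contribution is zero).  Missing beta
    entries contribute zero as well.
    """
    coefs = clock.coefficients
    present = coefs.index.intersection(matrix.index)
    missing = coefs.index.difference(matrix.index)
    if len(missing) and not drop_missing:
        raise ValueError(
            f"{len(missing)} clock markers absent from the matrix: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
        )
    sub = matrix.loc[present].to_numpy(dtype=float)
    sub = np.nan_to_num(sub, nan=0.0)
    linear = clock.intercept + coefs.loc[present].to_numpy() @ sub
    return pd.Series(clock.inverse_transform(linear), index=matrix.columns, name="predicted_age")


def signed_error_by_age(true_ages, predicted_ages, quantile: float = 0.9) -> float:
    """Mean signed error (predicted - true) among the oldest samples.

    "Oldest" means true age strictly above the given quantile of the true
    ages.  Negative values indicate systematic underprediction of old ages.
    """
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and predicted vectors must match")
    cut = np.quantile(t, quantile)
    top = t > cut
    if not top.any():
        raise ValueError("no samples above the requested age quantile")
    return float(np.mean(p[top] - t[top]))
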