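"""Probe-level filtering and mutual-information sample outlier removal.

Probe filtering removes blacklisted probes (SNP-overlapping, cross-reactive)
and probes with too many missing beta values.  Sample QC scores each sample
by the mutual information between its beta-value profile and the cohort mean
profile (probes paired positionally, both binned on [0, 1]); samples whose
score falls more than ``k_sd`` standard deviations below the cohort mean
score are flagged as outliers.  Only low scores flag: an outlier is a sample
whose probe-wise correspondence with the cohort has broken down.

Estimators follow the scikit-learn convention (rows = samples, columns =
probes); the module-level functions accept the probes x samples orientation
used by the on-disk TSV format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "mi_score",
    "filter_probes",
    "flag_outlier_samples",
    "ProbeFilter",
    "MutualInformationOutlierFilter",
]


def mi_score(sample_values, reference_values, bins: int = 10) -> float:
    """Plug-in mutual information (nats) between two positionally paired beta vectors.

    Both vectors are binned into ``bins`` equal-width bins on [0, 1] and the
    MI of the resulting joint histogram is returned.  Pairs with a missing
    entry in either vector are dropped.
    """
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no non-missing pairs to score")
    if x.size < bins:
        raise ValueError(f"need at least {bins} pairs for {bins} bins, got {x.size}")
    edges = np.linspace(0.0, 1.0, bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Remove blacklisted probes and probes with too many missing values.

    Parameters
    ----------
    blacklists : dict[str, list[str]] | list[str] | None
        Probe ids to drop, either a flat list or a mapping of reason
        (e.g. ``snp_overlap``, ``cross_reactive``) to id list.
    max_missing : int
        A probe is dropped when its missing count is strictly greater than
        this (the "> 10 missing" rule).

    Attributes
    ----------
    retained_probes_ : pd.Index
        Surviving probe ids, input order preserved.
    report_ : dict
        Removal counts per rule.
    """

    def __init__(self, blacklists=None, max_missing: int = 10):
        self.blacklists = blacklists
        self.max_missing = max_missing

    def _blacklist_map(self) -> dict[str, set]:
        if self.blacklists is None:
            return {}
        if isinstance(self.blacklists, dict):
            return {k: set(v) for k, v in self.blacklists.items()}
        return {"blacklist": set(self.blacklists)}

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ProbeFilter requires a DataFrame with probe-id columns")
        bl = self._blacklist_map()
        probes = X.columns
        removed_by: dict[str, int] = {}
        drop = pd.Series(False, index=probes)
        reason = pd.Series("", index=probes)
        for name, ids in bl.items():
            hit = probes.isin(ids) & ~drop.to_numpy()
            removed_by[name] = int(hit.sum())
            drop |= pd.Series(hit, index=probes)
            reason[hit] = name
        missing_counts = X.isna().sum(axis=0)
        hit = (missing_counts > self.max_missing) & ~drop
        removed_by["missing"] = int(hit.sum())
        reason[hit] = "missing"
        drop |= hit
        self.retained_probes_ = probes[~drop]
        if len(self.retained_probes_) == 0:
            worst = max(removed_by, key=removed_by.get)
            raise ValueError(
                f"no probes survive filtering; the '{worst}' rule removed the most "
                f"({removed_by[worst]} of {len(probes)})"
            )
        self.report_ = {
            "n_input": int(len(probes)),
            "n_retained": int(len(self.retained_probes_)),
            "removed": removed_by,
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_probes_")
        return X.loc[:, self.retained_probes_]


class MutualInformationOutlierFilter(BaseEstimator, OutlierMixin):
    """Flag samples whose MI against the cohort mean profile is anomalously low.

    The reference profile is the per-probe mean over samples (missing values
    excluded).  A sample is an outlier iff its MI score is below
    ``mean(scores) - k_sd * sd(scores)``.  The screen runs in a single pass;
    scores are not recomputed after removals.

    Attributes after :meth:`fit`: ``mi_scores_`` (per-sample MI, nats),
    ``threshold_``, ``flagged_`` (outlier sample ids), ``reference_``.
    """

    def __init__(self, bins: int = 10, k_sd: float = 3.0):
        self.bins = bins
        self.k_sd = k_sd

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples to estimate an outlier threshold")
        self.reference_ = X.mean(axis=0, skipna=True).to_numpy()
        scores = {
            sid: mi_score(row.to_numpy(dtype=float), self.reference_, bins=self.bins)
            for sid, row in X.iterrows()
        }
        self.mi_scores_ = pd.Series(scores, name="mi_score")
        mu = float(self.mi_scores_.mean())
        sd = float(self.mi_scores_.std(ddof=1))
        self.threshold_ = mu - self.k_sd * sd
        low = self.mi_scores_ < self.threshold_
        self.flagged_ = list(self.mi_scores_.index[low])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """-1 for flagged (outlier) samples, +1 otherwise (fitted samples only)."""
        check_is_fitted(self, "flagged_")
        flagged = set(self.flagged_)
        return np.array([-1 if sid in flagged else 1 for sid in X.index])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "flagged_")
        return X.loc[~X.index.isin(self.flagged_)]

    def report(self) -> dict:
        check_is_fitted(self, "flagged_")
        return {
            "n_samples": int(len(self.mi_scores_)),
            "mi_mean": float(self.mi_scores_.mean()),
            "mi_sd": float(self.mi_scores_.std(ddof=1)),
            "threshold": float(self.threshold_),
            "flagged": list(self.flagged_),
            "mi_scores": {k: float(v) for k, v in self.mi_scores_.items()},
        }


def filter_probes(
    matrix: pd.DataFrame, blacklists=None, max_missing: int = 10
) -> tuple[pd.DataFrame, dict]:
    """Apply probe filters to a probes x samples matrix; returns (filtered, report)."""
    f = ProbeFilter(blacklists=blacklists, max_missing=max_missing).fit(matrix.T)
    return matrix.loc[f.retained_probes_], f.report_


def flag_outlier_samples(
    matrix: pd.DataFrame, bins: int = 10, k_sd: float = 3.0
) -> tuple[pd.DataFrame, list[str], dict]:
    """MI outlier screen on a probes x samples matrix.

    Returns (matrix with flagged samples removed, flagged sample ids, report).
    """
    f = MutualInformationOutlierFilter(bins=bins, k_sd=k_sd).fit(matrix.T)
    kept = [s for s in matrix.columns if s not in set(f.flagged_)]
    return matrix.loc[:, kept], list(f.flagged_), f.report()
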