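"""Marker selection from running-median trajectories.

Per marker, the extreme statistics are the maximum fold change (largest
running median divided by the smallest, epsilon-guarded against zero
minima) and the maximum absolute change (largest minus smallest).  Both
extremes occur at the same pair of years, so a single two-sided t-test
between the raw beta values of the two extreme year groups serves both
selections.  Significance is controlled by Benjamini-Hochberg FDR over all
markers of the run, and a relative-SD filter removes markers whose group
spread is too large for the medians to be trusted.

Selection rules (defaults):
  fc_pass   : q < 0.05  AND  max_fc  >  2    AND  mean relative SD <= 0.5
  abs_pass  : q < 0.05  AND  max_delta >= 0.2 AND  mean relative SD <= 0.5
  overlap_pass : both.
The fold-change inequality is strict and the absolute-change one inclusive.

A Pearson-correlation baseline (raw beta vs age per marker, BH-controlled)
is provided for comparison: it flags markers by linear correlation alone,
including those whose total change is far too small to matter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from statsmodels.stats.multitest import multipletests

from .age_groups import (
    AgeGroupIndex,
    RunningMedianTransformer,
    mean_relative_sd,
)

__all__ = [
    "max_fold_change",
    "max_abs_change",
    "extremes_ttest",
    "bh_fdr",
    "select_markers",
    "pearson_selection",
    "genes_multi_marker",
    "MarkerSelector",
]

_MODES = ("fc", "abs", "overlap")


def _extreme_years(medians: pd.Series) -> tuple[int, int]:
    vals = medians.to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError("all running medians missing")
    year_min = int(medians.index[np.nanargmin(vals)])
    year_max = int(medians.index[np.nanargmax(vals)])
    return year_min, year_max


def max_fold_change(
    medians: pd.Series, epsilon: float = 1e-6
) -> tuple[float, tuple[int, int], bool]:
    """Maximum fold change of a running-median track.

    Returns (max_fc, (year of minimum, year of maximum), epsilon_guarded).
    ``max_fc = max / max(min, epsilon)``; the guard flag marks tracks whose
    minimum was below epsilon so the ratio is not trustworthy on its own.
    """
    if medians.size < 2:
        raise ValueError("need at least 2 retained years")
    year_min, year_max = _extreme_years(medians)
    lo = float(medians.loc[year_min])
    hi = float(medians.loc[year_max])
    guarded = lo < epsilon
    return hi / max(lo, epsilon), (year_min, year_max), guarded


def max_abs_change(medians: pd.Series) -> tuple[float, tuple[int, int]]:
    """Maximum absolute running-median change; extreme years coincide with the FC's."""
    if medians.size < 2:
        raise ValueError("need at least 2 retained years")
    year_min, year_max = _extreme_years(medians)
    return float(medians.loc[year_max] - medians.loc[year_min]), (year_min, year_max)


def extremes_ttest(
    matrix: pd.DataFrame,
    index: AgeGroupIndex,
    marker_id: str,
    fc_years: tuple[int, int],
    equal_var: bool = False,
) -> float:
    """Two-sided t-test between a marker's raw betas in the two extreme year groups.

    Welch's unequal-variance test by default.  Returns NaN when either group
    has fewer than two usable values or zero variance in both.
    """
    row = matrix.loc[marker_id].to_numpy(dtype=float)
    a = row[index.members_for(fc_years[0])]
    b = row[index.members_for(fc_years[1])]
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaN p-values stay NaN."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _score_markers(
    medians: pd.DataFrame,
    rel_sd: pd.DataFrame,
    matrix: pd.DataFrame,
    index: AgeGroupIndex,
    fc_threshold: float = 2.0,
    delta_threshold: float = 0.2,
    fdr: float = 0.05,
    rel_sd_max: float = 0.5,
    epsilon: float = 1e-6,
    equal_var: bool = False,
    rel_sd_scope: str = "all",
) -> pd.DataFrame:
    rows = []
    for marker in medians.index:
        track = medians.loc[marker].dropna()
        if track.size < 2:
            rows.append((marker, np.nan, -1, -1, np.nan, np.nan, False))
            continue
        fc, (y0, y1), guarded = max_fold_change(track, epsilon)
        delta, _ = max_abs_change(track)
        p = extremes_ttest(matrix, index, marker, (y0, y1), equal_var=equal_var)
        rows.append((marker, fc, y0, y1, delta, p, guarded))
    sel = pd.DataFrame(
        rows,
        columns=["marker_id", "max_fc", "year_min", "year_max", "max_delta", "t_p", "epsilon_guarded"],
    ).set_index("marker_id")
    fc_years = sel[["year_min", "year_max"]]
    sel["mean_rel_sd"] = mean_relative_sd(
        rel_sd, scope=rel_sd_scope, fc_years=fc_years if rel_sd_scope == "extremes" else None
    )
    sel["q"] = bh_fdr(sel["t_p"].to_numpy())
    sig = (sel["q"] < fdr) & (sel["mean_rel_sd"] <= rel_sd_max)
    sel["fc_pass"] = sig & (sel["max_fc"] > fc_threshold)
    sel["abs_pass"] = sig & (sel["max_delta"] >= delta_threshold)
    sel["overlap_pass"] = sel["fc_pass"] & sel["abs_pass"]
    return sel


def select_markers(
    medians: pd.DataFrame,
    rel_sd: pd.DataFrame,
    matrix: pd.DataFrame,
    index: AgeGroupIndex,
    fc_threshold: float = 2.0,
    delta_threshold: float = 0.2,
    fdr: float = 0.05,
    rel_sd_max: float = 0.5,
    mode: str = "fc",
    epsilon: float = 1e-6,
    equal_var: bool = False,
    rel_sd_scope: str = "all",
) -> pd.DataFrame:
    """Full per-marker selection table with pass flags and a ``selected`` column.

    ``medians``/``rel_sd`` are markers x retained years (from the running-median
    stage); ``matrix`` is the probes x samples beta table underlying them.
    ``mode`` picks which flag populates ``selected``: ``fc``, ``abs`` or
    ``overlap``.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown selection mode {mode!r}; expected one of {_MODES}")
    sel = _score_markers(
        medians, rel_sd, matrix, index,
        fc_threshold=fc_threshold, delta_threshold=delta_threshold, fdr=fdr,
        rel_sd_max=rel_sd_max, epsilon=epsilon, equal_var=equal_var,
        rel_sd_scope=rel_sd_scope,
    )
    sel["selected"] = sel[f"{mode}_pass"]
    return sel


def pearson_selection(matrix: pd.DataFrame, ages, fdr: float = 0.05) -> pd.DataFrame:
    """Per-marker Pearson correlation of raw beta with age, with BH control.

    Missing betas are dropped per marker.  A marker with zero beta variance
    gets r = 0 and p = 1 by convention.  Returns a DataFrame with columns
    ``r``, ``p``, ``q``, ``pearson_pass``.
    """
    ages = np.asarray(ages, dtype=float)
    values = matrix.to_numpy(dtype=float)
    n_markers = values.shape[0]
    r = np.zeros(n_markers)
    p = np.ones(n_markers)
    for i in range(n_markers):
        row = values[i]
        ok = ~np.isnan(row)
        x, a = row[ok], ages[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(a) == 0:
            continue
        ri = float(np.corrcoef(x, a)[0, 1])
        ri = max(-1.0, min(1.0, ri))
        df = x.size - 2
        if abs(ri) >= 1.0:
            pi = 0.0
        else:
            t = ri * np.sqrt(df / (1.0 - ri * ri))
            pi = 2.0 * stats.t.sf(abs(t), df)
        r[i], p[i] = ri, pi
    out = pd.DataFrame({"r": r, "p": p}, index=matrix.index)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["pearson_pass"] = out["q"] < fdr
    return out


def genes_multi_marker(selected_ids, probe_gene_map: pd.DataFrame) -> tuple[dict, dict]:
    """Group selected markers by gene; keep genes hit by at least two markers.

    A probe mapped to several genes counts for each.  Returns
    ``(genes, report)`` where ``genes`` maps gene id to its sorted supporting
    marker list and ``report`` holds mapped/unmapped counts.
    """
    selected = set(selected_ids)
    mapped = probe_gene_map[probe_gene_map["probe_id"].isin(selected)]
    by_gene: dict[str, list[str]] = {}
    for gene, grp in mapped.groupby("gene_id"):
        markers = sorted(set(grp["probe_id"]))
        if len(markers) >= 2:
            by_gene[gene] = markers
    n_mapped = mapped["probe_id"].nunique()
    report = {
        "n_selected": len(selected),
        "n_mapped": int(n_mapped),
        "n_unmapped": len(selected) - int(n_mapped),
        "n_genes_multi": len(by_gene),
    }
    return by_gene, report


class MarkerSelector(BaseEstimator, SelectorMixin):
    """Feature selector keeping markers with large, significant trajectory change.

    Scikit-learn style: ``fit(X, y)`` with X a samples x probes beta table and
    y the age vector; ``transform`` keeps the selected probe columns.  The
    full per-marker statistics table is available as ``selection_``.

    Parameters mirror the pipeline defaults: ``fraction`` of nearest samples
    per year group, ``edge_tolerance`` (years) for trimming edge groups,
    fold-change / absolute-change / FDR / relative-SD thresholds, and the
    selection ``mode`` (``fc``, ``abs`` or ``overlap``).
    """

    def __init__(
        self,
        fraction: float = 0.1,
        edge_tolerance: float = 2.0,
        fc_threshold: float = 2.0,
        delta_threshold: float = 0.2,
        fdr: float = 0.05,
        rel_sd_max: float = 0.5,
        mode: str = "fc",
        epsilon: float = 1e-6,
        equal_var: bool = False,
        rel_sd_scope: str = "all",
    ):
        self.fraction = fraction
        self.edge_tolerance = edge_tolerance
        self.fc_threshold = fc_threshold
        self.delta_threshold = delta_threshold
        self.fdr = fdr
        self.rel_sd_max = rel_sd_max
        self.mode = mode
        self.epsilon = epsilon
        self.equal_var = equal_var
        self.rel_sd_scope = rel_sd_scope

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("MarkerSelector.fit requires ages as y")
        if self.mode not in _MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}; expected one of {_MODES}")
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        rmt = RunningMedianTransformer(self.fraction, self.edge_tolerance)
        medians = rmt.fit_transform(X, np.asarray(y, dtype=float))
        self.running_medians_ = medians
        self.rel_sd_ = rmt.rel_sd_
        self.index_ = rmt.index_
        self.retained_years_ = rmt.retained_years_
        self.selection_ = select_markers(
            medians, rmt.rel_sd_, X.T, rmt.index_,
            fc_threshold=self.fc_threshold, delta_threshold=self.delta_threshold,
            fdr=self.fdr, rel_sd_max=self.rel_sd_max, mode=self.mode,
            epsilon=self.epsilon, equal_var=self.equal_var,
            rel_sd_scope=self.rel_sd_scope,
        )
        self.support_ = self.selection_["selected"].to_numpy(dtype=bool)
        self.selected_markers_ = list(self.selection_.index[self.support_])
        return self

    def _get_support_mask(self):
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
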