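"""Per-year closest-10% age groups and running-median trajectories.

For each integer year from the floor of the youngest age to the ceiling of
the oldest, the group holds the ``k = ceil(fraction * n)`` samples nearest
in age (ties broken by ascending sample index, for determinism).  Equal
group sizes give every year the same sampling weight regardless of the
cohort's age density.  Groups whose median member age strays from the year
they represent — an edge effect where samples are sparse — are trimmed.
Within each retained group the per-marker median ("running median") and the
relative standard deviation (SD / median) are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AgeGroupIndex",
    "build_age_groups",
    "trim_edge_groups",
    "compute_running_medians",
    "relative_sd",
    "mean_relative_sd",
    "RunningMedianTransformer",
]


@dataclass
class AgeGroupIndex:
    """Membership of the per-year nearest-k sample groups.

    ``members[i]`` are positional sample indices of the group for
    ``years[i]``; ``midpoints[i]`` is the median member age and
    ``inclusion_limits[i]`` the (min, max) member age.
    """

    years: np.ndarray
    members: list[np.ndarray]
    ages: np.ndarray
    sample_ids: list[str]
    k: int
    midpoints: np.ndarray
    inclusion_limits: list[tuple[float, float]]

    def members_for(self, year: int) -> np.ndarray:
        pos = int(np.searchsorted(self.years, year))
        if pos >= len(self.years) or self.years[pos] != year:
            raise KeyError(f"no age group for year {year}")
        return self.members[pos]

    def to_manifest(self) -> dict:
        return {
            "k": int(self.k),
            "years": self.years.tolist(),
            "midpoints": self.midpoints.tolist(),
            "inclusion_limits": [list(map(float, lim)) for lim in self.inclusion_limits],
            "members": {
                int(y): [self.sample_ids[j] for j in m]
                for y, m in zip(self.years, self.members)
            },
        }


def build_age_groups(ages, fraction: float = 0.1, sample_ids=None) -> AgeGroupIndex:
    """Build the per-year closest-``fraction`` groups over an age vector."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = ages.size
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    k = math.ceil(fraction * n)
    years = np.arange(math.floor(ages.min()), math.ceil(ages.max()) + 1)
    members: list[np.ndarray] = []
    midpoints = np.empty(len(years))
    limits: list[tuple[float, float]] = []
    idx = np.arange(n)
    for i, y in enumerate(years):
        # lexsort: primary key distance, secondary key original index
        order = np.lexsort((idx, np.abs(ages - y)))
        grp = order[:k]
        members.append(grp)
        midpoints[i] = float(np.median(ages[grp]))
        limits.append((float(ages[grp].min()), float(ages[grp].max())))
    return AgeGroupIndex(
        years=years,
        members=members,
        ages=ages,
        sample_ids=list(sample_ids),
        k=k,
        midpoints=midpoints,
        inclusion_limits=limits,
    )


def trim_edge_groups(index: AgeGroupIndex, tolerance: float = 2.0) -> np.ndarray:
    """Retain years whose group midpoint lies within ``tolerance`` years of the year."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    keep = np.abs(index.midpoints - index.years) <= tolerance
    retained = index.years[keep]
    if retained.size == 0:
        raise ValueError(
            "no age group has a midpoint within the tolerance of its year; "
            "increase edge_tolerance or provide a denser cohort"
        )
    return retained


def compute_running_medians(
    matrix: pd.DataFrame, index: AgeGroupIndex, retained=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker median beta within each retained year group.

    ``matrix`` is probes x samples with columns ordered as ``index.sample_ids``.
    Returns (medians, n_used), both markers x years.  A marker-year whose
    member values are all missing is NaN with ``n_used`` 0.
    """
    if retained is None:
        retained = index.years
    retained = np.asarray(retained)
    known = set(index.years.tolist())
    if not set(retained.tolist()) <= known:
        raise ValueError("retained years must be a subset of the index years")
    if list(matrix.columns) != list(index.sample_ids):
        matrix = matrix.loc[:, index.sample_ids]
    values = matrix.to_numpy(dtype=float)
    med = np.empty((values.shape[0], retained.size))
    n_used = np.empty((values.shape[0], retained.size), dtype=int)
    for j, y in enumerate(retained):
        grp = index.members_for(int(y))
        block = values[:, grp]
        with np.errstate(all="ignore"):
            med[:, j] = np.nanmedian(block, axis=1)
        n_used[:, j] = np.sum(~np.isnan(block), axis=1)
    years_idx = pd.Index(retained.astype(int), name="year")
    return (
        pd.DataFrame(med, index=matrix.index, columns=years_idx),
        pd.DataFrame(n_used, index=matrix.index, columns=years_idx),
    )


def relative_sd(
    matrix: pd.DataFrame, index: AgeGroupIndex, retained=None
) -> pd.DataFrame:
    """Per marker-year relative SD: sample SD (ddof=1) divided by the group median.

    A zero median with non-zero spread yields +inf, which downstream spread
    filters treat as failing.
    """
    if retained is None:
        retained = index.years
    retained = np.asarray(retained)
    if list(matrix.columns) != list(index.sample_ids):
        matrix = matrix.loc[:, index.sample_ids]
    values = matrix.to_numpy(dtype=float)
    out = np.empty((values.shape[0], retained.size))
    for j, y in enumerate(retained):
        grp = index.members_for(int(y))
        block = values[:, grp]
        with np.errstate(all="ignore"):
            sd = np.nanstd(block, axis=1, ddof=1)
            med = np.nanmedian(block, axis=1)
            rel = np.where(med != 0, sd / np.where(med != 0, med, 1.0), np.inf)
        out[:, j] = rel
    return pd.DataFrame(out, index=matrix.index, columns=pd.Index(retained.astype(int), name="year"))


def mean_relative_sd(
    rel_sd: pd.DataFrame, scope: str = "all", fc_years: pd.DataFrame | None = None
) -> pd.Series:
    """Average relative SD per marker.

    ``scope='all'`` averages over every retained year; ``scope='extremes'``
    averages only the two years at which the marker attains its extreme
    running medians (requires ``fc_years`` with columns ``year_min``,
    ``year_max``).
    """
    if scope == "all":
        return rel_sd.mean(axis=1)
    if scope == "extremes":
        if fc_years is None:
            raise ValueError("scope='extremes' requires fc_years")
        vals = np.empty(len(rel_sd))
        for i, marker in enumerate(rel_sd.index):
            y0 = int(fc_years.loc[marker, "year_min"])
            y1 = int(fc_years.loc[marker, "year_max"])
            vals[i] = float(np.mean([rel_sd.loc[marker, y0], rel_sd.loc[marker, y1]]))
        return pd.Series(vals, index=rel_sd.index)
    raise ValueError(f"unknown rel_sd scope {scope!r}")


class RunningMedianTransformer(BaseEstimator, TransformerMixin):
    """Transform a samples x probes beta table into marker x year running medians.

    ``fit`` consumes the age vector ``y`` to build the per-year nearest-k
    groups and trim edge years; ``transform`` emits the running-median table
    (markers x retained years).  Per-year relative SDs and usable counts are
    exposed as fitted attributes after ``transform``.
    """

    def __init__(self, fraction: float = 0.1, edge_tolerance: float = 2.0):
        self.fraction = fraction
        self.edge_tolerance = edge_tolerance

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("RunningMedianTransformer.fit requires ages as y")
        ids = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(y))]
        self.index_ = build_age_groups(np.asarray(y, dtype=float), self.fraction, sample_ids=ids)
        self.retained_years_ = trim_edge_groups(self.index_, self.edge_tolerance)
        self.age_range_ = (int(self.retained_years_.min()), int(self.retained_years_.max()))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "index_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        matrix = X.T  # probes x samples
        medians, n_used = compute_running_medians(matrix, self.index_, self.retained_years_)
        self.medians_ = medians
        self.n_used_ = n_used
        self.rel_sd_ = relative_sd(matrix, self.index_, self.retained_years_)
        return medians
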