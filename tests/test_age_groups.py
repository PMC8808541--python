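import math

import numpy as np
import pandas as pd
import pytest

from methylaging.age_groups import (
    RunningMedianTransformer,
    build_age_groups,
    compute_running_medians,
    mean_relative_sd,
    relative_sd,
    trim_edge_groups,
)
from methylaging.synthetic import TrajectorySpec, generate_beta_matrix, trajectory_eval


def brute_force_knearest(ages, year, k):
    """Independent oracle: sort by (distance, index), take k."""
    order = sorted(range(len(ages)), key=lambda i: (abs(ages[i] - year), i))
    return sorted(order[:k])


class TestBuildAgeGroups:
    def test_one_sample_per_year_matches_brute_force(self):
        ages = np.arange(1.0, 101.0)  # ages 1..100
        index = build_age_groups(ages, fraction=0.1)
        assert index.k == 10
        for y, members in zip(index.years, index.members):
            assert sorted(members) == brute_force_knearest(ages, y, 10)
        # year 50: distances tie at 45 and 55; the lower index (age 45) wins
        grp_ages = sorted(ages[index.members_for(50)])
        assert grp_ages == [45, 46, 47, 48, 49, 50, 51, 52, 53, 54]

    def test_group_size_is_ceil(self):
        index = build_age_groups(np.linspace(0, 80, 20), fraction=0.1)
        assert index.k == 2
        assert all(len(m) == 2 for m in index.members)

    def test_all_same_age_degenerate(self):
        index = build_age_groups(np.full(12, 40.0), fraction=0.25)
        assert list(index.years) == [40]
        assert np.all(index.midpoints == 40.0)

    def test_equal_sampling_invariant(self, rng):
        ages = rng.uniform(0, 90, 73)
        index = build_age_groups(ages, fraction=0.1)
        k = math.ceil(0.1 * 73)
        assert all(len(m) == k for m in index.members)

    def test_empty_ages_rejected(self):
        with pytest.raises(ValueError):
            build_age_groups([])


class TestTrimEdgeGroups:
    def test_permissive_tolerance_keeps_all(self, rng):
        index = build_age_groups(rng.uniform(0, 100, 500), fraction=0.1)
        dev = np.abs(index.midpoints - index.years).max()
        retained = trim_edge_groups(index, tolerance=dev)
        assert len(retained) == len(index.years)

    def test_sparse_edge_dropped(self):
        # one isolated young sample: its year group is dominated by much older
        # samples, the midpoint drifts far above the year, the year is trimmed
        ages = np.concatenate([[19.0], np.linspace(40, 90, 99)])
        index = build_age_groups(ages, fraction=0.1)
        retained = trim_edge_groups(index, tolerance=2.0)
        assert 19 not in retained
        mid = index.midpoints[list(index.years).index(19)]
        assert mid > 30

    def test_tolerance_zero_matches_brute_force(self):
        # brute force the exact-midpoint set; with an even group size the
        # median falls between two integers, so nothing survives and the
        # trim reports failure rather than an empty analysis range
        ages = np.arange(1.0, 101.0)
        index = build_age_groups(ages, fraction=0.1)
        expected = [
            y for y, m in zip(index.years, index.members) if np.median(ages[m]) == y
        ]
        assert expected == []
        with pytest.raises(ValueError, match="tolerance"):
            trim_edge_groups(index, tolerance=0.0)
        # odd group size: midpoints are attained ages, the exact set is non-empty
        index21 = build_age_groups(ages, fraction=0.21)  # k = 21
        expected21 = [
            y for y, m in zip(index21.years, index21.members) if np.median(ages[m]) == y
        ]
        assert expected21
        assert list(trim_edge_groups(index21, tolerance=0.0)) == expected21

    def test_nothing_retained_is_an_error(self):
        # all samples at age 0.5: both integer years are 0.5 y from the midpoint
        ages = np.full(10, 0.5)
        index = build_age_groups(ages, fraction=1.0)
        with pytest.raises(ValueError, match="tolerance"):
            trim_edge_groups(index, tolerance=0.4)


class TestRunningMedians:
    def _index(self, matrix, ages):
        return build_age_groups(ages, 0.1, sample_ids=list(matrix.columns))

    def test_constant_marker(self, noiseless_matrix):
        matrix, _, meta = noiseless_matrix
        index = self._index(matrix, meta["age"].to_numpy())
        med, n_used = compute_running_medians(matrix, index)
        assert np.allclose(med.loc["const"], 0.3)
        assert (n_used == index.k).all().all()

    def test_median_matches_sort_oracle(self):
        ages = np.array([30.0, 30.0, 30.0])
        matrix = pd.DataFrame([[0.1, 0.4, 0.2]], index=["m"], columns=["a", "b", "c"])
        index = build_age_groups(ages, fraction=1.0, sample_ids=["a", "b", "c"])
        med, _ = compute_running_medians(matrix, index)
        assert med.loc["m", 30] == sorted([0.1, 0.4, 0.2])[1]

    def test_even_count_mean_of_middle_two(self):
        ages = np.array([30.0, 30.0])
        matrix = pd.DataFrame([[0.1, 0.3]], index=["m"], columns=["a", "b"])
        index = build_age_groups(ages, fraction=1.0, sample_ids=["a", "b"])
        med, _ = compute_running_medians(matrix, index)
        assert med.loc["m", 30] == pytest.approx(0.2)

    def test_permutation_invariance(self, noiseless_matrix, rng):
        matrix, _, meta = noiseless_matrix
        ages = meta["age"].to_numpy()
        index = self._index(matrix, ages)
        med1, _ = compute_running_medians(matrix, index)
        perm = rng.permutation(len(ages))
        cols = [matrix.columns[i] for i in perm]
        index2 = build_age_groups(ages[perm], 0.1, sample_ids=cols)
        med2, _ = compute_running_medians(matrix[cols], index2)
        pd.testing.assert_frame_equal(med1, med2)

    def test_noiseless_median_tracks_trajectory(self, noiseless_matrix):
        matrix, truth, meta = noiseless_matrix
        ages = meta["age"].to_numpy()
        index = self._index(matrix, ages)
        retained = trim_edge_groups(index, 2.0)
        med, _ = compute_running_medians(matrix, index, retained)
        spec = truth.specs[2]  # sigmoid
        for j, y in enumerate(retained):
            pos = list(index.years).index(y)
            lo, hi = index.inclusion_limits[pos]
            band = [trajectory_eval(spec, a) for a in (lo, hi)]
            spread = max(band) - min(band)
            mid_val = trajectory_eval(spec, index.midpoints[pos])
            assert abs(med.loc["sig", y] - mid_val) <= spread + 1e-12

    def test_monotone_trajectory_gives_monotone_track(self, noiseless_matrix):
        matrix, _, meta = noiseless_matrix
        index = self._index(matrix, meta["age"].to_numpy())
        retained = trim_edge_groups(index, 2.0)
        med, _ = compute_running_medians(matrix, index, retained)
        assert (np.diff(med.loc["lin"].to_numpy()) >= -1e-12).all()
        assert (np.diff(med.loc["sig"].to_numpy()) >= -1e-12).all()

    def test_retained_subset_enforced(self, noiseless_matrix):
        matrix, _, meta = noiseless_matrix
        index = self._index(matrix, meta["age"].to_numpy())
        with pytest.raises(ValueError):
            compute_running_medians(matrix, index, retained=[99999])


class TestRelativeSd:
    def test_constant_groups_zero(self):
        ages = np.full(6, 50.0)
        matrix = pd.DataFrame([[0.4] * 6], index=["m"], columns=[f"s{i}" for i in range(6)])
        index = build_age_groups(ages, 1.0, sample_ids=list(matrix.columns))
        rs = relative_sd(matrix, index)
        assert rs.to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_formula_on_three_values(self):
        # {0.1, 0.2, 0.3}: SD 0.1, median 0.2 -> 0.5
        ages = np.full(3, 50.0)
        matrix = pd.DataFrame([[0.1, 0.2, 0.3]], index=["m"], columns=["a", "b", "c"])
        index = build_age_groups(ages, 1.0, sample_ids=["a", "b", "c"])
        rs = relative_sd(matrix, index)
        assert rs.loc["m", 50] == pytest.approx(0.5)

    def test_zero_median_is_infinite(self):
        ages = np.full(3, 50.0)
        matrix = pd.DataFrame([[0.0, 0.0, 0.3]], index=["m"], columns=["a", "b", "c"])
        index = build_age_groups(ages, 1.0, sample_ids=["a", "b", "c"])
        rs = relative_sd(matrix, index)
        assert np.isinf(rs.loc["m", 50])

    def test_scope_switch(self):
        rel = pd.DataFrame([[0.1, 0.9, 0.5]], index=["m"], columns=pd.Index([10, 20, 30], name="year"))
        fc_years = pd.DataFrame({"year_min": [10], "year_max": [30]}, index=["m"])
        assert mean_relative_sd(rel, "all").loc["m"] == pytest.approx(0.5)
        assert mean_relative_sd(rel, "extremes", fc_years).loc["m"] == pytest.approx(0.3)
        with pytest.raises(ValueError):
            mean_relative_sd(rel, "bogus")


def test_running_median_transformer_matches_functions(noiseless_matrix):
    matrix, _, meta = noiseless_matrix
    ages = meta["age"].to_numpy()
    rmt = RunningMedianTransformer(fraction=0.1, edge_tolerance=2.0)
    medians = rmt.fit_transform(matrix.T, ages)
    index = build_age_groups(ages, 0.1, sample_ids=list(matrix.columns))
    retained = trim_edge_groups(index, 2.0)
    expected, _ = compute_running_medians(matrix, index, retained)
    pd.testing.assert_frame_equal(medians, expected)
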