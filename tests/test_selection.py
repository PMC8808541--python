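import numpy as np
import pandas as pd
import pytest

from methylaging.age_groups import build_age_groups
from methylaging.selection import (
    MarkerSelector,
    bh_fdr,
    extremes_ttest,
    genes_multi_marker,
    max_abs_change,
    max_fold_change,
    pearson_selection,
    select_markers,
)
from methylaging.synthetic import TrajectorySpec, generate_beta_matrix, generate_cohort


def track(values, years=None):
    years = years if years is not None else range(len(values))
    return pd.Series(values, index=pd.Index(years, name="year"), dtype=float)


class TestExtremeStatistics:
    def test_fold_change_basic(self):
        fc, (y0, y1), guarded = max_fold_change(track([0.25, 0.1, 0.2]))
        assert fc == pytest.approx(2.5)
        assert (y0, y1) == (1, 0)
        assert not guarded

    def test_constant_track_fc_one_delta_zero(self):
        fc, _, _ = max_fold_change(track([0.3, 0.3, 0.3]))
        delta, _ = max_abs_change(track([0.3, 0.3, 0.3]))
        assert fc == 1.0
        assert delta == 0.0

    def test_epsilon_guard_flags_zero_minimum(self):
        fc, _, guarded = max_fold_change(track([0.0, 0.4]), epsilon=1e-6)
        assert guarded
        assert fc == pytest.approx(0.4 / 1e-6)

    def test_delta_basic_and_shared_extreme_years(self):
        t = track([0.10, 0.35, 0.2])
        delta, dy = max_abs_change(t)
        _, fy, _ = max_fold_change(t)
        assert delta == pytest.approx(0.25)
        assert dy == fy

    def test_delta_equals_pairwise_oracle(self, rng):
        vals = rng.uniform(0.05, 0.95, 15)
        t = track(vals)
        delta, _ = max_abs_change(t)
        oracle = max(abs(a - b) for a in vals for b in vals)
        assert delta == pytest.approx(oracle)

    def test_fc_at_least_one_delta_nonneg(self, rng):
        for _ in range(20):
            vals = rng.uniform(0.01, 1.0, 8)
            fc, _, _ = max_fold_change(track(vals))
            delta, _ = max_abs_change(track(vals))
            assert fc >= 1.0
            assert delta >= 0.0
            assert (delta == 0) == (fc == 1.0)


class TestExtremesTtest:
    def _setup(self, values_by_age):
        ages = np.concatenate([np.full(len(v), a) for a, v in values_by_age.items()])
        cols = [f"s{i}" for i in range(len(ages))]
        row = np.concatenate(list(values_by_age.values()))
        matrix = pd.DataFrame([row], index=["m"], columns=cols)
        index = build_age_groups(ages, fraction=len(ages) and max(2, 3) / len(ages), sample_ids=cols)
        return matrix, index

    def test_identical_groups_give_p_one(self):
        ages = np.full(6, 50.0)
        matrix = pd.DataFrame([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]], index=["m"],
                              columns=[f"s{i}" for i in range(6)])
        index = build_age_groups(ages, 1.0, sample_ids=list(matrix.columns))
        p = extremes_ttest(matrix, index, "m", (50, 50))
        assert p == pytest.approx(1.0)

    def test_strongly_separated_groups(self, rng):
        a = rng.normal(0.2, 0.01, 40)
        b = rng.normal(0.6, 0.01, 40)
        ages = np.concatenate([np.full(40, 20.0), np.full(40, 80.0)])
        cols = [f"s{i}" for i in range(80)]
        matrix = pd.DataFrame([np.concatenate([a, b])], index=["m"], columns=cols)
        index = build_age_groups(ages, fraction=0.5, sample_ids=cols)
        assert extremes_ttest(matrix, index, "m", (20, 80)) < 1e-10

    def test_matches_welch_formula_on_three_vs_three(self):
        a = np.array([0.10, 0.15, 0.20])
        b = np.array([0.30, 0.40, 0.35])
        # hand Welch: t and Welch-Satterthwaite df, p from the t survival fn
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t_stat), df)
        ages = np.array([20.0] * 3 + [80.0] * 3)
        cols = [f"s{i}" for i in range(6)]
        matrix = pd.DataFrame([np.concatenate([a, b])], index=["m"], columns=cols)
        index = build_age_groups(ages, fraction=0.5, sample_ids=cols)
        assert extremes_ttest(matrix, index, "m", (20, 80)) == pytest.approx(expected, rel=1e-10)


class TestBhFdr:
    def test_step_up_worked_example(self):
        # min over j>=i of p_j * m / j
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()


class TestPearsonSelection:
    def test_tiny_linear_drift_has_perfect_correlation(self):
        ages = np.linspace(0, 100, 60)
        cols = [f"s{i}" for i in range(60)]
        matrix = pd.DataFrame([0.10 + 0.0001 * ages], index=["m"], columns=cols)
        out = pearson_selection(matrix, ages)
        assert out.loc["m", "r"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["m", "pearson_pass"]

    def test_sign_flip(self):
        ages = np.linspace(0, 100, 30)
        matrix = pd.DataFrame([0.5 - 0.0001 * ages], index=["m"],
                              columns=[f"s{i}" for i in range(30)])
        assert pearson_selection(matrix, ages).loc["m", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_five_point_formula_oracle(self):
        ages = np.array([10.0, 20, 30, 50, 70])
        vals = np.array([0.2, 0.25, 0.23, 0.4, 0.38])
        r_oracle = np.cov(vals, ages, ddof=1)[0, 1] / (vals.std(ddof=1) * ages.std(ddof=1))
        matrix = pd.DataFrame([vals], index=["m"], columns=[f"s{i}" for i in range(5)])
        assert pearson_selection(matrix, ages).loc["m", "r"] == pytest.approx(r_oracle, rel=1e-12)

    def test_zero_variance_convention(self):
        ages = np.linspace(0, 100, 10)
        matrix = pd.DataFrame([[0.4] * 10], index=["m"], columns=[f"s{i}" for i in range(10)])
        out = pearson_selection(matrix, ages)
        assert out.loc["m", "r"] == 0.0
        assert out.loc["m", "p"] == 1.0


class TestGenesMultiMarker:
    MAP = pd.DataFrame(
        {"probe_id": ["m1", "m2", "m3", "m3"], "gene_id": ["G1", "G1", "G2", "G3"]}
    )

    def test_direct_count(self):
        genes, report = genes_multi_marker(["m1", "m2", "m3"], self.MAP)
        assert genes == {"G1": ["m1", "m2"]}
        assert report["n_genes_multi"] == 1

    def test_empty_selection(self):
        genes, _ = genes_multi_marker([], self.MAP)
        assert genes == {}

    def test_multi_gene_probe_counts_for_each(self):
        mapping = pd.DataFrame(
            {"probe_id": ["a", "a", "b", "c"], "gene_id": ["G1", "G2", "G1", "G2"]}
        )
        genes, _ = genes_multi_marker(["a", "b", "c"], mapping)
        assert genes == {"G1": ["a", "b"], "G2": ["a", "c"]}

    def test_unmapped_probes_counted(self):
        _, report = genes_multi_marker(["m1", "mystery"], self.MAP)
        assert report["n_unmapped"] == 1


class TestSelectMarkers:
    @pytest.fixture(scope="class")
    def cohort_selection(self):
        meta = generate_cohort(400, 0, 102, seed=31)
        specs = [
            TrajectorySpec("strong", "sigmoid", baseline=0.1, amplitude=0.3,
                           midpoint_age=50, steepness=0.2, noise_sd=0.02),
            TrajectorySpec("weaklin", "linear", baseline=0.4, slope=0.0001, noise_sd=0.005),
        ] + [
            TrajectorySpec(f"null{i}", "constant", baseline=0.5, noise_sd=0.03)
            for i in range(40)
        ]
        matrix, _ = generate_beta_matrix(meta, specs, seed=32)
        sel = MarkerSelector(mode="fc").fit(matrix.T, meta["age"].to_numpy())
        return sel.selection_

    def test_planted_sigmoid_passes_both_selections(self, cohort_selection):
        row = cohort_selection.loc["strong"]
        assert row["max_fc"] > 2
        assert row["max_delta"] >= 0.2
        assert row["q"] < 0.05
        assert row["fc_pass"] and row["abs_pass"] and row["overlap_pass"]

    def test_small_linear_drift_fails_change_thresholds(self, cohort_selection):
        row = cohort_selection.loc["weaklin"]
        assert row["max_fc"] < 2
        assert row["max_delta"] < 0.2
        assert not row["fc_pass"] and not row["abs_pass"]

    def test_overlap_subset_of_both(self, cohort_selection):
        sel = cohort_selection
        assert (sel["overlap_pass"] <= sel["fc_pass"]).all()
        assert (sel["overlap_pass"] <= sel["abs_pass"]).all()

    def test_unknown_mode_rejected(self, noiseless_matrix):
        matrix, _, meta = noiseless_matrix
        index = build_age_groups(meta["age"].to_numpy(), 0.1, sample_ids=list(matrix.columns))
        with pytest.raises(ValueError, match="mode"):
            select_markers(pd.DataFrame(), pd.DataFrame(), matrix, index, mode="bogus")


def test_marker_selector_transform_keeps_selected_columns():
    meta = generate_cohort(300, 0, 100, seed=41)
    specs = [
        TrajectorySpec("hit", "step", baseline=0.1, amplitude=0.4, midpoint_age=55, noise_sd=0.02)
    ] + [TrajectorySpec(f"null{i}", "constant", baseline=0.4, noise_sd=0.03) for i in range(20)]
    matrix, _ = generate_beta_matrix(meta, specs, seed=42)
    sel = MarkerSelector(mode="fc").fit(matrix.T, meta["age"].to_numpy())
    out = sel.transform(matrix.T)
    assert "hit" in sel.selected_markers_
    assert out.shape == (300, len(sel.selected_markers_))
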