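import math

import numpy as np
import pytest
from scipy import stats as sps

from fcnet.connectivity import ThresholdGrid, compute_fc_matrix
from fcnet.metrics import profile_subject
from fcnet.stats import (
    StatsConfig,
    SummaryStats,
    bonferroni_levels,
    chi_square_2x2,
    compare_groups,
    mann_whitney_u,
    partial_correlation,
    pearson_correlation,
    permutation_two_sample,
    two_sample_t,
)
from fcnet.synthetic import generate_cohort, null_config, \
    strong_lesion_config


class TestTwoSampleT:
    def test_welch_from_summary_triples(self):
        # cohort-table reproduction: (14.42, 6.86, 24) vs (29.21, 0.98, 19)
        res = two_sample_t(SummaryStats(14.42, 6.86, 24),
                           SummaryStats(29.21, 0.98, 19), variant="welch")
        assert res.statistic == pytest.approx(-10.43, abs=0.005)
        assert res.p_value < 1e-9

    def test_student_pooled_from_summary_triples(self):
        res = two_sample_t(SummaryStats(48.39, 10.66, 24),
                           SummaryStats(53.70, 9.34, 19), variant="student")
        assert res.statistic == pytest.approx(-1.71, abs=0.005)
        assert res.df == 41

    def test_matches_scipy_on_raw_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 15)
        ours = two_sample_t(a, b, variant="welch")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)
        ours_s = two_sample_t(a, b, variant="student")
        ref_s = sps.ttest_ind(a, b, equal_var=True)
        assert ours_s.statistic == pytest.approx(ref_s.statistic)
        assert ours_s.p_value == pytest.approx(ref_s.pvalue)

    def test_identical_groups_give_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(a, a, variant="welch")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_equal_means(self):
        with pytest.raises(ValueError, match="undefined"):
            two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0], variant="welch")


class TestChiSquare:
    def test_balanced_table_is_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        # E = 10 everywhere, sum (O-E)^2/E = 4 * 100/10 = 40
        res = chi_square_2x2([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_sex_distribution_table_uncorrected_and_yates(self):
        # 16:8 vs 10:9 hand computation; the published 0.48 matches
        # neither convention (documented mismatch)
        res = chi_square_2x2([[16, 8], [10, 9]])
        assert res.statistic == pytest.approx(0.873, abs=0.001)
        res_y = chi_square_2x2([[16, 8], [10, 9]], yates=True)
        assert res_y.statistic == pytest.approx(0.385, abs=0.001)

    def test_matches_scipy_contingency(self):
        table = [[12, 5], [7, 11]]
        ours = chi_square_2x2(table, yates=True)
        ref = sps.chi2_contingency(np.array(table), correction=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_samples_midrank(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n^2/2

    def test_interleaved_exact_enumeration(self):
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.statistic == 1.0
        # exact distribution over C(4,2)=6 orderings: P(U<=1)+P(U>=3)=4/6
        assert res.p_value == pytest.approx(2 / 3)
        assert res.method == "mann_whitney_u"


class TestPermutation:
    def test_exhaustive_toy_case(self):
        res = permutation_two_sample([1.0, 2.0], [10.0, 11.0])
        assert res.method == "permutation_t_exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_p_one(self):
        res = permutation_two_sample([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_addone_lower_bound(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 1, 30)
        b = rng.normal(-5, 1, 30)
        res = permutation_two_sample(a, b, n_perm=200, seed=0)
        assert res.p_value >= 1 / 201

    def test_sampled_close_to_exact_on_enumerable_design(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.8, 1, 6)
        b = rng.normal(0, 1, 6)
        exact = permutation_two_sample(a, b)  # C(12,6)=924 -> exhaustive
        # compare the sampled estimator on the same data via resampling
        t_obs = exact.statistic
        rng2 = np.random.default_rng(3)
        pooled = np.concatenate([a, b])
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm = rng2.permutation(12)
            x, y = pooled[perm[:6]], pooled[perm[6:]]
            t = (x.mean() - y.mean()) / math.sqrt(
                x.var(ddof=1) / 6 + y.var(ddof=1) / 6)
            hits += abs(t) >= abs(t_obs) - 1e-12
        sampled_p = (1 + hits) / (n_perm + 1)
        assert abs(sampled_p - exact.p_value) <= 0.02


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_r(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        x = np.arange(20.0)
        for _ in range(200):
            rs.append(pearson_correlation(
                x, rng.permutation(x)).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_partial_reduces_to_pearson_with_no_covariates(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=0.5, size=15)
        full = pearson_correlation(x, y)
        part = partial_correlation(x, y, np.empty((15, 0)))
        assert part.statistic == pytest.approx(full.statistic)
        assert part.p_value == pytest.approx(full.p_value)

    def test_partial_removes_confounder(self):
        rng = np.random.default_rng(6)
        n = 500
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        y = x + c
        res = partial_correlation(x, y, c)
        assert res.statistic > 0.95
        # raw correlation is diluted by the confounder
        assert pearson_correlation(x, y).statistic < res.statistic

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(7)
        n = 40
        df = pd.DataFrame({
            "x": rng.normal(size=n), "y": rng.normal(size=n),
            "c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-9)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, cov)

    def test_fully_explained_variable_rejected(self):
        rng = np.random.default_rng(9)
        c = rng.normal(size=20)
        x = 3 * c + 1  # zero residual variance
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="explained"):
            partial_correlation(x, y, c)


class TestBonferroni:
    def test_study_scale_levels(self):
        strict, liberal = bonferroni_levels(0.05, 264)
        assert strict == pytest.approx(0.05 / 264)
        assert round(strict, 6) == 0.000189
        assert liberal == pytest.approx(1 / 264)
        assert round(liberal, 4) == 0.0038

    def test_single_test_identity(self):
        strict, liberal = bonferroni_levels(0.05, 1)
        assert strict == 0.05
        assert liberal == 1.0


def _profiles_and_clinical(config, n_nulls=0):
    series, clinical = generate_cohort(config)
    grid = ThresholdGrid()
    profiles = [profile_subject(compute_fc_matrix(ts), grid,
                                n_nulls=n_nulls, seed=i)
                for i, ts in enumerate(series)]
    return profiles, clinical


@pytest.fixture(scope="module")
def lesioned():
    cfg = strong_lesion_config(
        seed=12, n_patients=8, n_controls=8, n_nodes=24,
        n_timepoints=120, module_sizes=(8, 8, 8),
        lesion_nodes=frozenset(range(8)))
    return _profiles_and_clinical(cfg)


class TestCompareGroups:

    def test_lesion_lowers_patient_eloc_auc(self, lesioned):
        profiles, clinical = lesioned
        table = compare_groups(profiles, clinical,
                               StatsConfig(n_perm=200, run_nodal=False))
        row = table.global_tests.set_index("metric").loc["Eloc"]
        assert row["mean_patient"] < row["mean_control"]

    def test_table_shapes_and_flags(self, lesioned):
        profiles, clinical = lesioned
        table = compare_groups(profiles, clinical, StatsConfig(n_perm=100))
        assert set(table.global_tests["metric"]) == {
            "Cp", "Lp", "Eglob", "Eloc"}  # no nulls -> no gamma/lambda/sigma
        assert len(table.nodal_tests) == 24 * 4
        strict, liberal = table.bonferroni
        flagged = table.nodal_tests
        assert ((flagged["p"] < strict) == flagged["flag_strict"]).all()
        assert ((flagged["p"] < liberal) == flagged["flag_liberal"]).all()

    def test_behavior_rows_only_for_significant_metrics(self, lesioned):
        profiles, clinical = lesioned
        table = compare_groups(profiles, clinical,
                               StatsConfig(n_perm=100, run_nodal=False))
        sig = set(table.global_tests.loc[table.global_tests.significant,
                                         "metric"])
        assert set(table.behavior["metric"]) <= sig

    def test_missing_group_rejected(self, lesioned):
        profiles, clinical = lesioned
        only_pat = clinical.copy()
        only_pat["group"] = "patient"
        with pytest.raises(ValueError, match="2 subjects per group"):
            compare_groups(profiles, only_pat, StatsConfig())

    def test_null_cohort_rarely_flags_nodes_at_strict_level(self):
        cfg = null_config(seed=33, n_patients=8, n_controls=8,
                          n_nodes=24, n_timepoints=120,
                          module_sizes=(8, 8, 8),
                          lesion_nodes=frozenset(range(8)))
        profiles, clinical = _profiles_and_clinical(cfg)
        table = compare_groups(profiles, clinical,
                               StatsConfig(n_perm=100, run_behavior=False))
        frac = table.nodal_tests["flag_strict"].mean()
        assert frac <= 0.05
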