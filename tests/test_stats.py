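"""Normality test, t-tests, correlation screening, standardized regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from achastroke import (
    StatsInputError,
    cohort_table,
    dagostino_pearson,
    generate_cohort,
    multiple_linear_regression,
    pearson_r,
    run_group_comparisons,
    screen_predictors,
    two_sample_t,
    two_sample_t_from_stats,
)


class TestDagostinoPearson:
    def test_small_sample_rejected(self):
        with pytest.raises(StatsInputError):
            dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsInputError):
            dagostino_pearson([2.0] * 20)

    def test_skewed_sample_rejected_with_power(self):
        """Exponential samples of n=100 are flagged non-normal >= 95% of
        the time."""
        rng = np.random.default_rng(4)
        rejections = sum(
            dagostino_pearson(rng.exponential(size=100))[1] < 0.05
            for _ in range(200)
        )
        assert rejections >= 0.95 * 200

    def test_statistic_is_chi2_with_2df(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        k2, p = dagostino_pearson(x)
        assert p == pytest.approx(sps.chi2.sf(k2, 2))


class TestTwoSampleT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = two_sample_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)
        assert df == 6

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_printed_group_summaries_reach_significance(self):
        """The permanent-occlusion strata summaries (n=6, 42.7 +/- 27.62 vs
        n=7, 144.5 +/- 11.72) give pooled t ~ 8.91 on 11 df, p < 0.0001;
        verified against scipy's summary-statistics implementation."""
        t, df, p = two_sample_t_from_stats(144.5, 11.72, 7, 42.7, 27.62, 6)
        assert df == 11
        assert t == pytest.approx(8.91, abs=0.01)
        assert p < 1e-4
        oracle = sps.ttest_ind_from_stats(
            144.5, 11.72, 7, 42.7, 27.62, 6, equal_var=True
        )
        assert t == pytest.approx(oracle.statistic, abs=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 3, 12)
        t, df, p = two_sample_t(a, b, variant="welch")
        oracle = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(oracle.statistic)
        assert p == pytest.approx(oracle.pvalue)
        t2, df2, p2 = two_sample_t_from_stats(
            a.mean(), a.std(ddof=1), 10, b.mean(), b.std(ddof=1), 12, "welch"
        )
        assert (t2, df2, p2) == pytest.approx((t, df, p))

    def test_agrees_with_exact_permutation_oracle(self):
        """On small samples the pooled-t p-value tracks the exact
        enumeration permutation p-value (coarse agreement: the t reference
        distribution is an approximation at n=5+5)."""
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 5), rng.normal(1.2, 1, 5)
        t_obs, _, p_t = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        stats = []
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, bool)
            mask[list(idx)] = True
            stats.append(two_sample_t(pooled[mask], pooled[~mask])[0])
        p_perm = np.mean(np.abs(stats) >= abs(t_obs) - 1e-12)
        assert p_t == pytest.approx(p_perm, abs=0.05)

    def test_insufficient_n_rejected(self):
        with pytest.raises(StatsInputError):
            two_sample_t([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_variable_rejected(self):
        with pytest.raises(StatsInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_point_biserial_equals_ssb_sst_closed_form(self):
        """On a binary indicator, Pearson r equals sign(M1-M0) *
        sqrt(SSB/SST) from the one-way decomposition — checked on 100
        random small tables."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(6, 30)
            g = rng.integers(0, 2, n)
            if g.min() == g.max():
                g[0] = 1 - g[0]
            y = rng.normal(g * rng.uniform(0, 3), 1.0)
            r, _ = pearson_r(g.astype(float), y)
            m = y.mean()
            m0, m1 = y[g == 0].mean(), y[g == 1].mean()
            ssb = (g == 0).sum() * (m0 - m) ** 2 + (g == 1).sum() * (m1 - m) ** 2
            sst = ((y - m) ** 2).sum()
            oracle = np.sign(m1 - m0) * np.sqrt(ssb / sst)
            assert r == pytest.approx(oracle, abs=1e-12)


class TestScreening:
    def test_response_as_its_own_predictor_included(self, cohort):
        table = cohort_table(cohort)
        table["self"] = table["infarct_volume_mm3"]
        [entry] = screen_predictors(table, candidates=("self",))
        assert entry.included and entry.p < 1e-20

    def test_noise_predictor_type_one_rate(self):
        """A pure-noise candidate passes the p<0.10 screen about 10% of the
        time (3 SE band over 1,000 replicates)."""
        rng = np.random.default_rng(10)
        n = 28
        hits = 0
        reps = 1000
        y = rng.normal(size=n)
        for _ in range(reps):
            x = rng.normal(size=n)
            df = pd.DataFrame({"infarct_volume_mm3": y, "noise": x})
            hits += screen_predictors(df, candidates=("noise",))[0].included
        assert abs(hits / reps - 0.10) < 3 * np.sqrt(0.1 * 0.9 / reps)

    def test_default_cohort_screens_in_duration_and_achao_not_weight(self, cohort):
        table = cohort_table(cohort)
        entries = {e.name: e for e in screen_predictors(table)}
        assert entries["acha_occluded"].included
        assert entries["duration_h"].included
        assert not entries["weight_g"].included

    def test_constant_candidate_noted_not_crashed(self, cohort):
        table = cohort_table(cohort)
        table["flat"] = 1.0
        [entry] = screen_predictors(table, candidates=("flat",))
        assert not entry.included and "constant" in entry.note


class TestRegression:
    def test_single_predictor_beta_equals_pearson_r(self, cohort):
        table = cohort_table(cohort)
        reg = multiple_linear_regression(table, predictors=("duration_h",))
        r, p = pearson_r(table["duration_h"], table["infarct_volume_mm3"])
        assert reg.beta["duration_h"] == pytest.approx(r, abs=1e-12)
        assert reg.pvalues["duration_h"] == pytest.approx(p, rel=1e-9)

    def test_orthogonal_predictors_recover_marginal_correlations(self):
        """With exactly orthogonal centred predictors each standardized
        coefficient equals its marginal r, and adjusted r^2 matches the
        closed form 1 - (1-r^2)(n-1)/(n-p-1)."""
        n = 24
        t = np.arange(n) - (n - 1) / 2
        x1 = t
        x2 = t**2 - np.mean(t**2)
        assert np.dot(x1, x2) == pytest.approx(0.0)
        rng = np.random.default_rng(11)
        y = 0.8 * x1 / np.std(x1) + 0.4 * x2 / np.std(x2) + rng.normal(size=n)
        df = pd.DataFrame({"infarct_volume_mm3": y, "x1": x1, "x2": x2})
        reg = multiple_linear_regression(df, predictors=("x1", "x2"))
        r1, _ = pearson_r(x1, y)
        r2, _ = pearson_r(x2, y)
        assert reg.beta["x1"] == pytest.approx(r1, abs=1e-10)
        assert reg.beta["x2"] == pytest.approx(r2, abs=1e-10)
        expected_adj = 1 - (1 - reg.r_squared) * (n - 1) / (n - 2 - 1)
        assert reg.adjusted_r_squared == pytest.approx(expected_adj, abs=1e-12)

    def test_betas_match_normal_equations_oracle(self):
        """Standardized coefficients agree to 1e-10 with directly solving
        the normal equations on z-scored data, over 50 random designs."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            cols = {f"x{j}": X[:, j] for j in range(p)}
            df = pd.DataFrame({"infarct_volume_mm3": y, **cols})
            reg = multiple_linear_regression(df, predictors=tuple(cols))
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            oracle = np.linalg.solve(Z.T @ Z, Z.T @ zy)
            got = np.array([reg.beta[f"x{j}"] for j in range(p)])
            assert np.allclose(got, oracle, atol=1e-10)
            assert reg.adjusted_r_squared <= reg.r_squared + 1e-15

    def test_collinear_design_rejected(self, cohort):
        table = cohort_table(cohort)
        table["dup"] = table["duration_h"] * 2.0
        with pytest.raises(StatsInputError):
            multiple_linear_regression(table, predictors=("duration_h", "dup"))

    def test_sign_recovery_over_seeds(self):
        """Across 200 seeded default cohorts the regression recovers
        beta(AChAo) > beta(duration) > 0 in at least 95% of seeds."""
        from achastroke import CohortConfig

        hits = 0
        for seed in range(200):
            table = cohort_table(generate_cohort(CohortConfig(), seed))
            reg = multiple_linear_regression(
                table, predictors=("duration_h", "acha_occluded")
            )
            hits += reg.beta["acha_occluded"] > reg.beta["duration_h"] > 0
        assert hits >= 0.95 * 200


class TestGroupComparisons:
    def test_small_cells_not_analyzed(self, cohort):
        comps = {c.name: c for c in run_group_comparisons(cohort_table(cohort))}
        assert not comps["1h"].analyzed and "n=2" in comps["1h"].reason
        assert not comps["2h"].analyzed and "n=1" in comps["2h"].reason
        assert comps["permanent"].analyzed
        assert comps["pooled"].analyzed

    def test_permanent_and_pooled_strongly_significant(self, cohort):
        comps = {c.name: c for c in run_group_comparisons(cohort_table(cohort))}
        assert comps["permanent"].p < 1e-3
        assert comps["pooled"].p < 1e-4
        # AChAo cell mean exceeds the non-AChAo cell mean
        assert comps["pooled"].mean_achao > comps["pooled"].mean_no_achao

    def test_row_order_and_single_group_table(self, cohort):
        table = cohort_table(cohort)
        names = [c.name for c in run_group_comparisons(table)]
        assert names == ["1h", "2h", "permanent", "pooled"]
        one = table[table["group"] == "permanent"]
        names = [c.name for c in run_group_comparisons(one)]
        assert names == ["permanent", "pooled"]

    def test_normality_reported_at_feasible_scope(self, cohort):
        comps = {c.name: c for c in run_group_comparisons(cohort_table(cohort))}
        # permanent cells are n=6/7 (< 8): tested at group scope
        assert "group" in comps["permanent"].normality
        # pooled cells are n=18/10: tested per cell
        assert {"no_achao", "achao"} <= set(comps["pooled"].normality)
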