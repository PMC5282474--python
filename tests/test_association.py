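"""Biomarker statistics: ANOVA/Tukey, normality, correlation, regression,
standardized differences and group-size planning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualpet.association import (
    anova_tukey,
    fit_regression,
    group_size,
    ks_normality,
    pearson,
    pooled_sd,
    standardized_difference_series,
)


class TestAnovaTukey:
    def test_identical_groups_give_zero_f_unit_p(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        res = anova_tukey(vals, groups)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert (res.pairwise["p_adj"] > 0.999).all()

    def test_two_groups_tukey_equals_pooled_t(self, rng):
        # With two groups the studentized range collapses to sqrt(2)|t|,
        # so the Tukey adjusted p equals the two-sample pooled-t p.
        a = rng.normal(size=10)
        b = rng.normal(loc=0.8, size=12)
        res = anova_tukey(np.concatenate([a, b]), np.repeat(["a", "b"], [10, 12]))
        t_p = stats.ttest_ind(a, b).pvalue
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-8)

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(11)
        groups = np.repeat(["a", "b", "c", "d"], 8)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            res = anova_tukey(rng.normal(size=32), groups)
            rejections += res.p < 0.05
        rate = rejections / n_rep
        # 0.05 +- ~3.4 binomial SEs
        assert 0.017 <= rate <= 0.083

    def test_tukey_p_not_below_unadjusted_t(self, rng):
        vals = rng.normal(size=24) + np.repeat([0.0, 0.5, 1.0], 8)
        groups = np.repeat(["a", "b", "c"], 8)
        res = anova_tukey(vals, groups)
        for _, row in res.pairwise.iterrows():
            a = vals[groups == row.group_a]
            b = vals[groups == row.group_b]
            assert row.p_adj >= stats.ttest_ind(a, b).pvalue - 1e-12

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_tukey(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(4)
        rate = np.mean([ks_normality(rng.normal(size=50)) < 0.05 for _ in range(100)])
        assert rate <= 0.15

    def test_lognormal_samples_usually_rejected(self):
        rng = np.random.default_rng(5)
        rate = np.mean(
            [ks_normality(np.exp(rng.normal(size=50, scale=1.0))) < 0.05 for _ in range(50)]
        )
        assert rate > 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.full(10, 3.3))


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))

    def test_estimates_true_correlation(self):
        # Bivariate normal with rho = 0.9: the mean estimate over replicates
        # stays inside the Fisher-z 95% band of the truth.
        rng = np.random.default_rng(6)
        rho, n, reps = 0.9, 25, 1000
        rs = []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
            rs.append(pearson(x, y)[0])
        z = np.arctanh(rs).mean()
        half = 1.96 / math.sqrt(n - 3) / math.sqrt(reps)
        assert abs(np.tanh(z) - rho) < np.tanh(abs(z) + half) - np.tanh(abs(z)) + 0.01


class TestRegression:
    def test_outcome_equal_to_predictor(self):
        df = pd.DataFrame({"y": np.arange(10.0), "x": np.arange(10.0)})
        res = fit_regression(df, "y", ["x"])
        assert res.beta["x"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_beta_squared_is_r_squared(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=40), "age": rng.normal(size=40)})
        res = fit_regression(df, "y", ["age"])
        assert res.beta["age"] ** 2 == pytest.approx(res.r_squared, abs=1e-10)
        r, _ = pearson(df["age"], df["y"])
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_orthogonal_predictor_beta_near_zero(self, rng):
        n = 4000
        df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        res = fit_regression(df, "y", ["x"])
        assert abs(res.beta["x"]) < 0.06

    def test_collinear_predictors_named(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"y": rng.normal(size=20), "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_regression(df, "y", ["a", "b"])


class TestPooledSd:
    def test_equal_sds(self):
        assert pooled_sd(1.7, 5, 1.7, 9) == pytest.approx(1.7)

    def test_hand_example(self):
        assert pooled_sd(0.0, 4, 2.0, 4) == pytest.approx(math.sqrt(2.0))

    def test_equals_sd_of_concatenated_centered_groups(self, rng):
        a = rng.normal(size=7)
        b = rng.normal(loc=5, size=9)
        centered = np.concatenate([a - a.mean(), b - b.mean()])
        oracle = math.sqrt((centered**2).sum() / (len(centered) - 2))
        assert pooled_sd(a.std(ddof=1), 7, b.std(ddof=1), 9) == pytest.approx(oracle)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pooled_sd(1.0, 1, 1.0, 4)
        with pytest.raises(ValueError):
            pooled_sd(-1.0, 4, 1.0, 4)


class TestStandardizedDifferences:
    @staticmethod
    def _tg(ages, means, sds, n=8):
        return pd.DataFrame(
            {"age_months": ages, "mean": means, "sd": sds, "n": [n] * len(ages)}
        )

    def test_flat_wt_gives_constant_d(self):
        tg = self._tg([5, 8, 13], [10.0] * 3, [2.0] * 3)
        series = standardized_difference_series(tg, ((6.0, 6.0), (18.0, 6.0)))
        assert np.allclose(series.table["d"], 2.0)

    def test_midpoint_interpolation(self):
        tg = self._tg([12.0], [6.0], [1.0])
        series = standardized_difference_series(tg, ((6.0, 4.0), (18.0, 8.0)))
        assert series.table.loc[0, "wt_interp"] == pytest.approx(6.0)
        assert series.table.loc[0, "d"] == pytest.approx(0.0)

    def test_matches_spreadsheet_recomputation(self, rng):
        ages = [5.0, 8.0, 13.0, 16.0]
        means = rng.normal(10, 2, size=4)
        sds = rng.uniform(0.5, 2.0, size=4)
        (a1, m1), (a2, m2) = (6.0, 7.0), (18.0, 9.5)
        series = standardized_difference_series(
            self._tg(ages, means, sds), ((a1, m1), (a2, m2))
        )
        for i, a in enumerate(ages):
            interp = m1 + (m2 - m1) * (a - a1) / (a2 - a1)
            expected = (means[i] - interp) / sds[i]
            assert series.table.loc[i, "d"] == pytest.approx(expected, abs=1e-12)

    def test_pooled_sd_flag_for_adjacent_ages(self):
        tg = self._tg([5.0, 8.0], [10.0, 12.0], [0.0, 2.0], n=4)
        with pytest.raises(ValueError, match="pool"):
            standardized_difference_series(tg, ((6.0, 6.0), (18.0, 6.0)))
        series = standardized_difference_series(
            tg, ((6.0, 6.0), (18.0, 6.0)), pool_ages=(5.0, 8.0)
        )
        assert np.allclose(series.table["sd_used"], math.sqrt(2.0))

    def test_invariant_to_unit_rescaling(self, rng):
        ages = [5.0, 16.0]
        means = [12.0, 20.0]
        sds = [2.0, 3.0]
        base = standardized_difference_series(
            self._tg(ages, means, sds), ((6.0, 8.0), (18.0, 10.0))
        )
        c = 37.5
        scaled = standardized_difference_series(
            self._tg(ages, [c * m for m in means], [c * s for s in sds]),
            ((6.0, c * 8.0), (18.0, c * 10.0)),
        )
        assert np.allclose(base.table["d"], scaled.table["d"], atol=1e-12)


class TestGroupSize:
    def test_huge_effect_needs_minimum_group(self):
        assert group_size(0.05, 0.8, 50.0) == 2

    def test_monotone_nonincreasing_in_effect_size(self):
        ns = [group_size(0.05, 0.8, d) for d in (0.5, 0.8, 1.2, 2.0, 5.0)]
        assert ns == sorted(ns, reverse=True)

    def test_returned_n_verified_by_simulation(self):
        # Monte-Carlo oracle: the test's rejection rate crosses 80% exactly
        # at the returned n for d = 2, alpha = 0.05 two-sided.
        d, alpha = 2.0, 0.05
        n = group_size(alpha, 0.8, d)
        rng = np.random.default_rng(12)

        def mc_power(m, reps=4000):
            rej = 0
            for _ in range(reps):
                a = rng.normal(loc=d, size=m)
                b = rng.normal(size=m)
                rej += stats.ttest_ind(a, b).pvalue < alpha
            return rej / reps

        assert mc_power(n) >= 0.8 - 0.025
        assert mc_power(n - 1) < 0.8 + 0.025

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            group_size(0.0, 0.8, 1.0)
        with pytest.raises(ValueError):
            group_size(0.05, 0.8, 0.0)
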