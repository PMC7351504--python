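"""Group statistics: adjusted tests, FDR, partial correlation, summary tests."""

import numpy as np
import pytest
from scipy import stats

from covnet.gstats import (
    adjusted_two_sample_test,
    bh_fdr,
    chisq_2x2,
    paired_test,
    partial_correlation,
    summary_anova,
    summary_ttest,
)


class TestAdjustedTwoSampleTest:
    def test_reduces_to_pooled_t_without_covariates(self, rng):
        y = rng.standard_normal(60)
        g = np.array(["A"] * 30 + ["B"] * 30)
        res = adjusted_two_sample_test(y, g)
        t, p = stats.ttest_ind(y[30:], y[:30], equal_var=True)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_explicit_ols_oracle_with_confounding(self, rng):
        n = 80
        g = np.array(["HC"] * 40 + ["PD"] * 40)
        age = rng.normal(60, 8, n) + 3 * (g == "PD")  # confounded covariate
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.5 * (g == "PD") + 0.05 * age - 0.2 * sex + rng.standard_normal(n)
        res = adjusted_two_sample_test(y, g, np.column_stack([age, sex]))
        X = np.column_stack([np.ones(n), (g == "PD").astype(float), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.effect == pytest.approx(beta[1], abs=1e-8)
        assert res.t == pytest.approx(beta[1] / se, abs=1e-8)

    def test_permutation_null_p_uniform(self, rng):
        # under label permutation the p-value must be uniform
        n = 40
        y = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        base = np.array(["A"] * 20 + ["B"] * 20)
        ps = []
        for _ in range(1000):
            g = rng.permutation(base)
            ps.append(adjusted_two_sample_test(y, g, cov).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_singular_design_rejected(self, rng):
        y = rng.standard_normal(20)
        g = np.array(["A"] * 10 + ["B"] * 10)
        cov = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="singular"):
            adjusted_two_sample_test(y, g, cov)


class TestPairedTest:
    def test_no_change_gives_t0_p1(self, rng):
        x = rng.standard_normal(20)
        res = paired_test(x, x.copy())
        assert res.t == 0.0 and res.p == 1.0 and not res.undefined

    def test_constant_nonzero_difference_flagged(self, rng):
        x = rng.standard_normal(10)
        res = paired_test(x, x + 1.0)
        assert res.undefined and np.isnan(res.p)

    def test_shift_detected_with_high_power(self, rng):
        base = rng.standard_normal(51)
        fup = base + 1.0 + rng.standard_normal(51)
        res = paired_test(base, fup)
        assert res.p < 1e-6 and res.effect > 0

    def test_matches_textbook_formula(self, rng):
        b, f = rng.standard_normal((2, 15))
        res = paired_test(b, f)
        d = f - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(15))
        p = 2 * stats.t.sf(abs(t), 14)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)


class TestBhFdr:
    @staticmethod
    def _oracle(pvals, alpha):
        # literal step-up: find largest i with p_(i) <= i/m * alpha
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = np.asarray(pvals)[order]
        passed = [i for i in range(m) if ranked[i] <= (i + 1) / m * alpha]
        reject = np.zeros(m, bool)
        if passed:
            reject[order[:passed[-1] + 1]] = True
        q = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        qvals = np.empty(m)
        qvals[order] = np.minimum(q, 1.0)
        return qvals, reject

    def test_published_family_of_14(self):
        # two small network p-values inside a family of 14 comparisons
        pvals = [0.021, 0.009] + [1.0] * 12
        q, rej = bh_fdr(pvals, 0.05)
        oq, orej = self._oracle(pvals, 0.05)
        assert np.allclose(q, oq, atol=1e-12)
        assert np.array_equal(rej, orej)

    def test_random_families_match_oracle(self, rng):
        for _ in range(100):
            m = rng.integers(1, 30)
            pvals = rng.random(m)
            q, rej = bh_fdr(pvals, 0.05)
            oq, orej = self._oracle(pvals, 0.05)
            assert np.allclose(q, oq, atol=1e-12)
            assert np.array_equal(rej, orej)

    def test_degenerate_families(self):
        q, rej = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not rej.any()
        q, rej = bh_fdr([0.03], 0.05)
        assert q[0] == pytest.approx(0.03) and rej[0]


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariate_association(self, rng):
        n = 200
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, 2))  # independent of x, y
        r, p = partial_correlation(x, y, cov)
        rp, _ = stats.pearsonr(x, y)
        assert r == pytest.approx(rp, abs=0.02)

    def test_confound_driven_association_removed(self, rng):
        n = 300
        c = rng.standard_normal(n)
        x = c + 0.1 * rng.standard_normal(n)
        y = c + 0.1 * rng.standard_normal(n)
        raw = stats.pearsonr(x, y)[0]
        r, _ = partial_correlation(x, y, c[:, None])
        assert raw > 0.9
        assert abs(r) < 0.15

    def test_matches_residualize_then_correlate_oracle(self, rng):
        n = 100
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, 2))
        r, p = partial_correlation(x, y, cov)
        X = np.column_stack([np.ones(n), cov])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        rx, ry = x - H @ x, y - H @ y
        r_o = np.corrcoef(rx, ry)[0, 1]
        df = n - 2 - 2
        t_o = r_o * np.sqrt(df / (1 - r_o**2))
        p_o = 2 * stats.t.sf(abs(t_o), df)
        assert r == pytest.approx(r_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        # independent reference implementation
        import pandas as pd
        import pingouin as pg

        n = 120
        x, y = rng.standard_normal((2, n))
        c1, c2 = rng.standard_normal((2, n))
        df = pd.DataFrame({"x": x + 0.5 * c1, "y": y + 0.3 * c1, "c1": c1, "c2": c2})
        r, p = partial_correlation(df["x"].values, df["y"].values,
                                   df[["c1", "c2"]].values)
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestSummaryTests:
    def test_equal_means_null(self):
        t, df, p = summary_ttest(5.0, 1.0, 20, 5.0, 2.0, 30)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_age_row_reproduced(self):
        # cross-sectional vs longitudinal patient groups, age in years
        _, _, p = summary_ttest(59.77, 9.08, 100, 60.49, 8.19, 51)
        assert round(p, 3) == 0.635

    def test_summary_matches_raw_data_pooled_t(self, rng):
        a = rng.normal(10, 2, 200)
        b = rng.normal(11, 2, 150)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_s, _, p_s = summary_ttest(a.mean(), a.std(ddof=1), 200,
                                    b.mean(), b.std(ddof=1), 150)
        assert t_s == pytest.approx(t_raw, abs=1e-10)
        assert p_s == pytest.approx(p_raw, abs=1e-10)

    def test_anova_identical_groups_null(self):
        F, _, _, p = summary_anova([(5, 1, 20), (5, 1, 20), (5, 1, 20)])
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_published_three_group_age_reproduced(self):
        F, df1, df2, p = summary_anova([(60.49, 8.19, 51), (62.45, 8.11, 51),
                                        (59.76, 7.63, 70)])
        assert round(p, 3) == 0.179

    def test_two_group_anova_equals_t_squared(self):
        t, _, p_t = summary_ttest(10.0, 2.0, 30, 11.0, 2.5, 40)
        F, _, _, p_F = summary_anova([(10.0, 2.0, 30), (11.0, 2.5, 40)])
        assert F == pytest.approx(t**2, abs=1e-10)
        assert p_F == pytest.approx(p_t, abs=1e-10)


class TestChisq2x2:
    def test_proportional_table_null(self):
        chi2, p = chisq_2x2(10, 20, 20, 40)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        chi2, _ = chisq_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)

    def test_matches_expected_counts_formula(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            chi2, p = chisq_2x2(a, b, c, d)
            n = a + b + c + d
            oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(oracle, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2(0, 0, 5, 5)
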