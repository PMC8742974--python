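"""Statistical battery: ANOVA decomposition, Pearson/Bonferroni, chi-square,
regression with standardized betas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from trabscope.stats import (StatsConfig, chisq_2x2, lv_rv_regression,
                             one_way_anova_p, pearson_with_bonferroni,
                             two_factor_anova)


class TestTwoFactorAnova:
    def test_all_equal_gives_f0_p1(self):
        an = two_factor_anova(np.full((4, 3), 2.5))
        assert (an.f_a, an.p_a, an.f_b, an.p_b) == (0.0, 1.0, 0.0, 1.0)

    def test_hand_worked_3x3(self):
        tab = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 3.0, 3.0]])
        an = two_factor_anova(tab)
        grand = tab.mean()
        ss_a = 3 * ((tab.mean(axis=1) - grand) ** 2).sum()
        ss_b = 3 * ((tab.mean(axis=0) - grand) ** 2).sum()
        ss_t = ((tab - grand) ** 2).sum()
        ss_e = ss_t - ss_a - ss_b
        f_b = (ss_b / 2) / (ss_e / 4)
        assert an.f_b == pytest.approx(f_b, abs=1e-10)
        assert an.p_b == pytest.approx(float(sps.f.sf(f_b, 2, 4)), abs=1e-10)

    def test_partition_exact(self):
        rng = np.random.default_rng(3)
        tab = rng.normal(size=(6, 4))
        an = two_factor_anova(tab)
        assert an.ss_total == pytest.approx(an.ss_a + an.ss_b + an.ss_error,
                                            abs=1e-9)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(8)
        tab = rng.normal(size=(5, 3))
        an = two_factor_anova(tab)
        rows = [{"v": tab[i, j], "a": f"a{i}", "b": f"b{j}"}
                for i in range(5) for j in range(3)]
        fit = ols("v ~ C(a) + C(b)", pd.DataFrame(rows)).fit()
        ref = sm.stats.anova_lm(fit)
        assert an.f_a == pytest.approx(float(ref["F"].iloc[0]))
        assert an.f_b == pytest.approx(float(ref["F"].iloc[1]))

    def test_large_shift_detected(self):
        # a strong resolution-like effect must come out highly significant
        rng = np.random.default_rng(1)
        base = rng.uniform(5, 15, size=12)
        tab = np.stack([base, base * 0.9, base * 0.45], axis=1)
        an = two_factor_anova(tab)
        assert an.p_b < 1e-3

    def test_dataframe_long_form_and_replicates(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(4):
            for r in ("x", "y"):
                for t in range(2):
                    rows.append({"value": rng.normal(), "sample": s,
                                 "resolution": r, "traj": t})
        df = pd.DataFrame(rows)
        a1 = two_factor_anova(df)
        cellmeans = df.groupby(["sample", "resolution"])["value"].mean() \
                      .unstack().to_numpy()
        a2 = two_factor_anova(cellmeans)
        assert a1.f_b == pytest.approx(a2.f_b)
        a3 = two_factor_anova(df, average_replicates=False)
        assert a3.df_error == 16 - 1 - 3 - 1

    def test_missing_cells_rejected(self):
        df = pd.DataFrame([{"value": 1.0, "sample": 0, "resolution": "x"},
                           {"value": 2.0, "sample": 1, "resolution": "y"}])
        with pytest.raises(ValueError, match="complete"):
            two_factor_anova(df)


class TestPearsonBonferroni:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        df = pearson_with_bonferroni({1: (x, 2 * x)})
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_formula(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 0.0])
        df = pearson_with_bonferroni({1: (x, y)})
        # closed form: r = cov / (sd_x sd_y)
        r = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert df["r"].iloc[0] == pytest.approx(r)

    def test_bonferroni_threshold(self):
        # p = 0.004 is not significant against 0.05/16 = 0.003125
        cfg = StatsConfig(alpha=0.05, bonferroni_m=16)
        assert cfg.bonferroni_threshold == pytest.approx(0.05 / 16)
        assert not (0.004 < cfg.bonferroni_threshold)

    def test_flags_subset_of_uncorrected(self):
        rng = np.random.default_rng(5)
        pairs = {s: (rng.normal(size=8),
                     rng.normal(size=8)) for s in range(1, 17)}
        df = pearson_with_bonferroni(pairs)
        assert ((~df["significant"]) | (df["p"] < 0.05)).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_bonferroni({1: (np.ones(5), np.arange(5.0))})


class TestChiSquare:
    def test_equal_proportions_zero(self):
        stat, p = chisq_2x2(10, 90, 10, 90)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_toy_table_closed_form(self):
        stat, _ = chisq_2x2(3, 1, 1, 3)
        assert stat == pytest.approx(2.0)

    def test_archive_prevalence_not_significant(self):
        # 4/629 vs 1/483 excessively trabeculated hearts across two archives
        stat, p = chisq_2x2(4, 625, 1, 482)
        assert p > 0.05

    def test_continuity_correction_differs(self):
        s0, _ = chisq_2x2(4, 625, 1, 482)
        s1, _ = chisq_2x2(4, 625, 1, 482, correction=True)
        assert s1 < s0

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_shortcut_equals_observed_expected_sum(self, counts):
        a, b, c, d = counts
        stat, _ = chisq_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], dtype=float)
        n = obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        assert stat == pytest.approx(float(((obs - exp) ** 2 / exp).sum()),
                                     rel=1e-10)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(0, 0, 5, 5)


class TestRegression:
    @staticmethod
    def volumes(n, seed, beta_rvt=0.0):
        rng = np.random.default_rng(seed)
        lv_c = rng.normal(100, 20, n)
        rv_c = rng.normal(30, 6, n)
        rv_t = rng.normal(25, 5, n)
        lv_t = 5 + 0.2 * lv_c + beta_rvt * rv_t + rng.normal(0, 5, n)
        return pd.DataFrame({"lv_trab": lv_t, "lv_compact": lv_c,
                             "rv_trab": rv_t, "rv_compact": rv_c})

    def test_identity_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"lv_trab": x, "lv_compact": x,
                           "rv_trab": rng.normal(size=30),
                           "rv_compact": rng.normal(size=30)})
        r = lv_rv_regression(df)
        assert r.standardized_betas["lv_compact"] == pytest.approx(1.0,
                                                                   abs=1e-8)
        assert r.adjusted_R2 == pytest.approx(1.0, abs=1e-8)

    def test_coefficient_recovery(self):
        df = self.volumes(100, seed=1, beta_rvt=0.8)
        r = lv_rv_regression(df)
        import statsmodels.api as sm
        X = sm.add_constant(df[["lv_compact", "rv_trab", "rv_compact"]])
        se = sm.OLS(df["lv_trab"], X).fit().bse["rv_trab"]
        assert abs(r.betas["rv_trab"] - 0.8) < 2 * se

    def test_null_predictor_rejection_rate(self):
        # under independence the RV-trabecular p-value is uniform: the
        # rejection rate over repeated cohorts stays near alpha
        rej = sum(lv_rv_regression(self.volumes(17, seed=s)).p_values["rv_trab"]
                  < 0.05 for s in range(200))
        assert rej / 200 <= 0.10

    def test_normality_gate_reported(self):
        r = lv_rv_regression(self.volumes(40, seed=2))
        assert 0.0 <= r.normality_p <= 1.0
        assert r.adjusted_R2 <= r.R2

    def test_residual_screen(self):
        r = lv_rv_regression(self.volumes(60, seed=3))
        lo, hi = r.residual_range
        assert r.residuals_within_bound == (max(abs(lo), abs(hi)) <= 3.0)

    def test_too_few_hearts_rejected(self):
        with pytest.raises(ValueError):
            lv_rv_regression(self.volumes(4, seed=0))


def test_one_way_anova_identical_groups_p1():
    assert one_way_anova_p([np.ones(5), np.ones(4)]) == 1.0
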