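import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fukomys.errors import StatsError
from fukomys.specimens import (
    adult_mask,
    anova_tukey_bonferroni,
    bonferroni,
    dimorphism_t_test,
    group_summary,
    load_specimen_table,
    manova_pillai,
    pooled_t_test,
    sex_mask,
)


@pytest.fixture(scope="module")
def table():
    return load_specimen_table()


def t_test_reference(a, b):
    """Textbook pooled two-sample t, coded independently."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestGroupSummary:
    def test_brute_force_arithmetic(self):
        df = pd.DataFrame(
            {"body_weight_g": [10.0, 20.0, 30.0], "species": ["x"] * 3}
        )
        s = group_summary(df, df["species"] == "x")
        assert s.mean == pytest.approx(20.0, abs=1e-12)
        assert s.sem == pytest.approx(np.std([10, 20, 30], ddof=1) / np.sqrt(3),
                                      abs=1e-12)
        assert (s.minimum, s.maximum) == (10.0, 30.0)

    def test_single_record_no_sem(self):
        df = pd.DataFrame({"body_weight_g": [42.0]})
        s = group_summary(df, [True])
        assert s.n == 1 and s.sem is None

    def test_empty_selection_rejected(self, table):
        with pytest.raises(StatsError):
            group_summary(table, table["species"] == "no-such-species")

    def test_hanangensis_adults(self, table):
        """Adults (known age class != 1) of the Hanang/Mbulu species."""
        s = group_summary(
            table, adult_mask(table, "F. hanangensis", "exclude_class1")
        )
        assert s.n == 30
        assert s.mean == pytest.approx(83.4, abs=0.05)
        assert s.sem == pytest.approx(5.6, abs=0.05)
        assert (s.minimum, s.maximum) == (35.0, 140.0)

    def test_livingstoni_adults(self, table):
        s = group_summary(
            table, adult_mask(table, "F. livingstoni", "class2_plus")
        )
        assert s.n == 4
        assert s.mean == pytest.approx(55.0, abs=0.05)
        assert s.sem == pytest.approx(8.9, abs=0.05)

    def test_sex_specific_means(self, table):
        adults = adult_mask(table, "F. hanangensis", "exclude_class1")
        males = group_summary(table, adults & sex_mask(table, "male"))
        females = group_summary(table, adults & sex_mask(table, "female"))
        assert (males.n, females.n) == (19, 10)
        assert males.mean == pytest.approx(90.8, abs=0.05)
        assert females.mean == pytest.approx(72.5, abs=0.05)


class TestPooledT:
    def test_identical_groups(self):
        r = pooled_t_test([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert r.value == 0.0 and r.p_value == 1.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(8)
        a = rng.normal(50, 10, 14)
        b = rng.normal(45, 12, 9)
        r = pooled_t_test(a, b)
        t_ref, p_ref = t_test_reference(a, b)
        assert r.value == pytest.approx(t_ref, abs=1e-10)
        assert r.p_value == pytest.approx(p_ref, abs=1e-10)
        assert r.df == (21,)

    def test_matches_welch_when_balanced(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        pooled = pooled_t_test(a, b)
        t_w, _ = sps.ttest_ind(a, b, equal_var=False)
        # equal n: pooled and Welch statistics coincide
        assert pooled.value == pytest.approx(t_w, abs=1e-10)

    def test_dimorphism_test_on_fixture(self, table):
        r = dimorphism_t_test(table)
        assert r.value == pytest.approx(1.575, abs=0.001)
        assert r.df == (27,)
        assert r.p_value == pytest.approx(0.127, abs=0.001)

    def test_degenerate_group_rejected(self):
        with pytest.raises(StatsError):
            pooled_t_test([1.0], [2.0, 3.0])


class TestManova:
    def test_univariate_reduction_matches_anova(self):
        """With one response, Pillai = SSB/(SSB+SSW) and F equals the
        one-way ANOVA F (hand-computed H and E oracle)."""
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.2, 1, 12)])
        g = np.array(["a"] * 10 + ["b"] * 12)
        res = manova_pillai(y[:, None], g)
        grand = y.mean()
        ssb = sum(
            (y[g == k].mean() - grand) ** 2 * (g == k).sum() for k in "ab"
        )
        ssw = sum(((y[g == k] - y[g == k].mean()) ** 2).sum() for k in "ab")
        assert res.value == pytest.approx(ssb / (ssb + ssw), abs=1e-10)
        f_anova, p_anova = sps.f_oneway(y[g == "a"], y[g == "b"])
        # recover F from the MANOVA table df
        df1, df2 = res.df
        v = res.value
        f_manova = (v / df1) / ((1 - v) / df2)
        assert f_manova == pytest.approx(f_anova, rel=1e-8)
        assert res.p_value == pytest.approx(p_anova, abs=1e-10)

    def test_identical_groups_zero_trace(self):
        rng = np.random.default_rng(2)
        block = rng.normal(0, 1, (6, 3))
        y = np.vstack([block, block])  # both groups identical in all responses
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = manova_pillai(y, g)
        assert res.value == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_multivariate(self):
        """Cross-check Pillai's trace and its F against statsmodels MANOVA
        on a multivariate two-group problem."""
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(11)
        y = np.hstack([
            np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 12)])[:, None],
            rng.normal(0, 1, (22, 1)),
            rng.normal(0, 1, (22, 1)),
        ])
        g = np.array(["a"] * 10 + ["b"] * 12)
        res = manova_pillai(y, g)
        x = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float)
        x.insert(0, "i", 1.0)
        mv = MANOVA(endog=y, exog=np.asarray(x))
        row = mv.mv_test(hypotheses=[("group", np.array([[0.0, 1.0]]))])
        stat = row.results["group"]["stat"].loc["Pillai's trace"]
        assert res.value == pytest.approx(float(stat["Value"]), abs=1e-10)
        assert res.df == (float(stat["Num DF"]), float(stat["Den DF"]))
        assert res.p_value == pytest.approx(float(stat["Pr > F"]), abs=1e-10)

    def test_trace_bounded(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, (30, 4))
        g = np.repeat(["a", "b", "c"], 10)
        res = manova_pillai(y, g)
        assert 0 <= res.value <= min(2, 4)

    def test_missing_values_rejected(self):
        y = np.array([[1.0, np.nan], [2.0, 3.0], [2.0, 3.0], [1.0, 2.0]])
        with pytest.raises(StatsError):
            manova_pillai(y, np.array(["a", "a", "b", "b"]))


class TestAnovaTukeyBonferroni:
    def test_equal_means_not_significant(self):
        rng = np.random.default_rng(3)
        base = rng.normal(10, 1, 12)
        resp = pd.DataFrame({"m1": np.tile(base, 3)})
        g = np.repeat(["a", "b", "c"], 12)
        out = anova_tukey_bonferroni(resp, g, m_tests=23)
        assert (~out["significant"]).all()

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.03, 23) == pytest.approx(0.69)
        assert bonferroni(0.2, 23) == 1.0

    def test_planted_difference_direction(self):
        rng = np.random.default_rng(6)
        resp = pd.DataFrame({
            "molar_breadth": np.concatenate([
                rng.normal(2.30, 0.07, 10),  # larger in the third species
                rng.normal(1.90, 0.05, 10),
                rng.normal(1.87, 0.05, 10),
            ])
        })
        g = np.repeat(["whytei", "hanangensis", "livingstoni"], 10)
        out = anova_tukey_bonferroni(resp, g, m_tests=3)
        w_vs_h = out[(out["group1"] == "hanangensis") & (out["group2"] == "whytei")]
        assert w_vs_h["mean_diff"].iloc[0] > 0
        assert w_vs_h["significant"].iloc[0]

    def test_small_group_excluded_with_warning(self):
        resp = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        g = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning):
            out = anova_tukey_bonferroni(resp, g)
        assert set(out["group1"]) | set(out["group2"]) == {"a", "b"}
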