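"""Statistics module against closed-form and brute-force oracles, plus
cross-checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ephyskit.stats import (fisher_plsd, one_way_anova, rm_anova, t_test,
                            two_way_anova)


def _pooled_t_brute(x, y):
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
           / (nx + ny - 2))
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return t, p


class TestTTest:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 17)
        r = t_test(x, y)
        t_ref, p_ref = _pooled_t_brute(x, y)
        assert r.t == pytest.approx(t_ref, rel=1e-10)
        assert r.p == pytest.approx(p_ref, rel=1e-10)

    def test_paired_identical_samples(self):
        x = np.arange(5.0)
        r = t_test(x, x, paired=True)
        assert r.t == 0.0 and r.p == 1.0

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 9), rng.normal(0, 3, 21)
        r = t_test(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, rel=1e-10)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_p_close_to_permutation_null(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0.0, 1.0, 15), rng.normal(0.6, 1.0, 15)
        r = t_test(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 100_000
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[order]
        px, py = perm[:, :15], perm[:, 15:]
        sp2 = (np.var(px, axis=1, ddof=1) + np.var(py, axis=1, ddof=1)) / 2
        t_perm = (px.mean(axis=1) - py.mean(axis=1)) \
            / np.sqrt(sp2 * (2 / 15))
        p_perm = np.mean(np.abs(t_perm) >= abs(r.t))
        mc_err = 3 * np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / n_perm)
        assert r.p == pytest.approx(p_perm, abs=max(0.01, mc_err))

    def test_zero_variance_equal_means(self):
        r = t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert r.t == 0.0 and r.p == 1.0


class TestOneWay:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
        values = np.concatenate([x, y])
        groups = ["a"] * 10 + ["b"] * 14
        res = one_way_anova(values, groups)
        t = t_test(x, y)
        assert res.table.loc["group", "F"] == pytest.approx(t.t ** 2,
                                                            rel=1e-8)
        assert res.p_value("group") == pytest.approx(t.p, rel=1e-8)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        samples = [rng.normal(m, 1, n) for m, n in ((0, 8), (0.5, 11),
                                                    (1.2, 7))]
        values = np.concatenate(samples)
        groups = np.repeat(["a", "b", "c"], [8, 11, 7])
        res = one_way_anova(values, groups)
        ref = sps.f_oneway(*samples)
        assert res.table.loc["group", "F"] == pytest.approx(ref.statistic,
                                                            rel=1e-10)
        assert res.p_value("group") == pytest.approx(ref.pvalue, rel=1e-10)


def _balanced_twoway_brute(df, value, fa, fb):
    """Textbook cell-means decomposition, exact for balanced designs."""
    grand = df[value].mean()
    ss_a = sum(len(sub) * (sub[value].mean() - grand) ** 2
               for _, sub in df.groupby(fa))
    ss_b = sum(len(sub) * (sub[value].mean() - grand) ** 2
               for _, sub in df.groupby(fb))
    ss_cells = sum(len(sub) * (sub[value].mean() - grand) ** 2
                   for _, sub in df.groupby([fa, fb]))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((sub[value] - sub[value].mean()) ** 2).sum()
                 for _, sub in df.groupby([fa, fb]))
    return ss_a, ss_b, ss_ab, ss_err


class TestTwoWay:
    @pytest.fixture()
    def balanced(self):
        rng = np.random.default_rng(12)
        rows = []
        for a in ("wt", "mut"):
            for b in (3, 4, 5):
                mu = (a == "mut") * 0.8 + 0.3 * b
                for _ in range(5):
                    rows.append([a, b, mu + rng.normal()])
        return pd.DataFrame(rows, columns=["geno", "week", "y"])

    def test_balanced_matches_cell_means_decomposition(self, balanced):
        res = two_way_anova(balanced, "y", "geno", "week")
        ss_a, ss_b, ss_ab, ss_err = _balanced_twoway_brute(
            balanced, "y", "geno", "week")
        assert res.table.loc["geno", "ss"] == pytest.approx(ss_a, rel=1e-8)
        assert res.table.loc["week", "ss"] == pytest.approx(ss_b, rel=1e-8)
        assert res.table.loc["geno:week", "ss"] == pytest.approx(ss_ab,
                                                                 rel=1e-8)
        assert res.table.loc["error", "ss"] == pytest.approx(ss_err,
                                                             rel=1e-8)
        # dfs sum to N - 1
        assert res.table["df"].sum() == len(balanced) - 1

    def test_unbalanced_type3_matches_statsmodels(self, balanced):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        df = balanced.drop(index=[0, 1, 7]).reset_index(drop=True)
        res = two_way_anova(df, "y", "geno", "week")
        fit = ols("y ~ C(geno, Sum) * C(week, Sum)", data=df).fit()
        ref = statsmodels.stats.anova_lm(fit, typ=3)
        assert res.table.loc["geno", "F"] == pytest.approx(
            ref.loc["C(geno, Sum)", "F"], rel=1e-6)
        assert res.table.loc["week", "F"] == pytest.approx(
            ref.loc["C(week, Sum)", "F"], rel=1e-6)
        assert res.table.loc["geno:week", "F"] == pytest.approx(
            ref.loc["C(geno, Sum):C(week, Sum)", "F"], rel=1e-6)

    def test_additive_noiseless_interaction_is_zero(self):
        rows = [[a, b, 2.0 * (a == "x") + 3.0 * b]
                for a in ("x", "y") for b in (0, 1) for _ in range(4)]
        df = pd.DataFrame(rows, columns=["fa", "fb", "y"])
        res = two_way_anova(df, "y", "fa", "fb")
        assert res.table.loc["fa:fb", "ss"] == pytest.approx(0.0, abs=1e-16)

    def test_duplicated_groups_give_null_factor(self):
        # identical data replicated in every cell: no effect anywhere
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 4)
        rows = [[a, b, base[i]] for a in ("g1", "g2")
                for b in ("u", "v") for i in range(4)]
        df = pd.DataFrame(rows, columns=["fa", "fb", "y"])
        res = two_way_anova(df, "y", "fa", "fb")
        assert res.table.loc["fa", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value("fa") == pytest.approx(1.0, abs=1e-9)

    def test_empty_cell_raises_with_cell_name(self):
        df = pd.DataFrame({"fa": ["x", "x", "y"], "fb": [0, 1, 0],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fa=y.*fb=1"):
            two_way_anova(df, "y", "fa", "fb")

    def test_label_permutation_invariance(self, balanced):
        res = two_way_anova(balanced, "y", "geno", "week")
        renamed = balanced.assign(
            geno=balanced["geno"].map({"wt": "B", "mut": "A"}))
        res2 = two_way_anova(renamed, "y", "geno", "week")
        for eff, eff2 in (("geno", "geno"), ("week", "week")):
            assert res.table.loc[eff, "F"] == pytest.approx(
                res2.table.loc[eff2, "F"], rel=1e-9)


def _rm_brute(df, value, between, within, subject):
    """Balanced mixed-design decomposition from cell/marginal means."""
    t = df[within].nunique()
    grand = df[value].mean()
    subj_means = df.groupby(subject)[value].mean()
    subj_group = df.groupby(subject)[between].first()
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    group_means = df.groupby(between)[value].mean()
    n_per_group = df.groupby(between)[subject].nunique()
    ss_group = t * sum(n_per_group[g] * (group_means[g] - grand) ** 2
                       for g in group_means.index)
    ss_subj = ss_between_subj - ss_group
    ss_total = ((df[value] - grand) ** 2).sum()
    ss_within_subj = ss_total - ss_between_subj
    time_means = df.groupby(within)[value].mean()
    n_subj = df[subject].nunique()
    ss_time = n_subj * ((time_means - grand) ** 2).sum()
    cell = df.groupby([between, within])[value].mean()
    ss_cells = sum(n_per_group[g] * (cell[(g, w)] - grand) ** 2
                   for g, w in cell.index)
    ss_inter = ss_cells - ss_group - ss_time
    ss_err = ss_within_subj - ss_time - ss_inter
    return ss_group, ss_subj, ss_time, ss_inter, ss_err


class TestRMAnova:
    @pytest.fixture()
    def wells(self):
        rng = np.random.default_rng(21)
        rows = []
        for g in ("ctrl", "var"):
            for s in range(15):
                subj_eff = rng.normal(0, 0.5)
                for d in range(8):
                    mu = 0.3 * d + (g == "var") * (0.5 + 0.1 * d)
                    rows.append([g, d, f"{g}{s}", mu + subj_eff
                                 + rng.normal(0, 0.4)])
        return pd.DataFrame(rows, columns=["geno", "day", "well", "y"])

    def test_matches_cell_means_decomposition(self, wells):
        res = rm_anova(wells, "y", "geno", "day", "well")
        ss = _rm_brute(wells, "y", "geno", "day", "well")
        for name, val in zip(["geno", "subject(group)", "day", "geno:day",
                              "subject:within"], ss):
            assert res.table.loc[name, "ss"] == pytest.approx(val, rel=1e-6)
        assert int(res.table.loc["geno", "df"]) == 1
        assert int(res.table.loc["subject:within"]["df"]) == 28 * 7

    def test_matches_pingouin_mixed_anova(self, wells):
        pg = pytest.importorskip("pingouin")
        res = rm_anova(wells, "y", "geno", "day", "well")
        ref = pg.mixed_anova(data=wells, dv="y", between="geno",
                             within="day", subject="well")
        ref = ref.set_index("Source")
        assert res.table.loc["geno", "F"] == pytest.approx(
            ref.loc["geno", "F"], rel=1e-6)
        assert res.table.loc["day", "F"] == pytest.approx(
            ref.loc["day", "F"], rel=1e-6)
        assert res.table.loc["geno:day", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_constant_within_factor_gives_zero_f(self):
        rows = [[g, d, f"{g}{s}", 1.0 * s + (g == "b")]
                for g in ("a", "b") for s in range(4) for d in (0, 1)]
        df = pd.DataFrame(rows, columns=["g", "d", "subj", "y"])
        res = rm_anova(df, "y", "g", "d", "subj")
        assert res.table.loc["d", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_2x2_interaction_equals_paired_difference_t_squared(self):
        rng = np.random.default_rng(30)
        rows = []
        diffs = {"a": [], "b": []}
        for g in ("a", "b"):
            for s in range(10):
                y0 = rng.normal(0, 1)
                y1 = y0 + rng.normal(0.5 if g == "b" else 0.0, 0.7)
                rows += [[g, 0, f"{g}{s}", y0], [g, 1, f"{g}{s}", y1]]
                diffs[g].append(y1 - y0)
        df = pd.DataFrame(rows, columns=["g", "d", "subj", "y"])
        res = rm_anova(df, "y", "g", "d", "subj")
        t = t_test(diffs["a"], diffs["b"])
        assert res.table.loc["g:d", "F"] == pytest.approx(t.t ** 2,
                                                          rel=1e-8)

    def test_incomplete_subjects_dropped(self, wells):
        broken = wells.drop(wells[(wells.well == "ctrl0")
                                  & (wells.day > 3)].index)
        res = rm_anova(broken, "y", "geno", "day", "well")
        assert res.n_dropped_subjects == 1


class TestFisherPLSD:
    @pytest.fixture()
    def three_groups(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(m, 1, 10)
                                 for m in (0.0, 0.4, 1.6)])
        groups = np.repeat(["a", "b", "c"], 10)
        return values, groups

    def test_pairwise_p_match_direct_pooled_t(self, three_groups):
        values, groups = three_groups
        anova = one_way_anova(values, groups)
        post = fisher_plsd(values, groups, anova)
        ms_e = anova.table.loc["error", "ms"]
        df_e = anova.table.loc["error", "df"]
        for _, row in post.table.iterrows():
            xi = values[groups == row["group_a"]]
            xj = values[groups == row["group_b"]]
            se = np.sqrt(ms_e * (1 / len(xi) + 1 / len(xj)))
            t_ref = (xi.mean() - xj.mean()) / se
            p_ref = 2 * sps.t.sf(abs(t_ref), df_e)
            assert row["t"] == pytest.approx(t_ref, rel=1e-8)
            assert row["p"] == pytest.approx(p_ref, rel=1e-8)

    def test_protection_blocks_nonsignificant_omnibus(self):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        anova = one_way_anova(values, groups)
        assert anova.p_value("group") > 0.05
        post = fisher_plsd(values, groups, anova)
        assert post.table.empty and post.protected

    def test_identical_means_no_significant_pairs(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        post = fisher_plsd(values, groups, protected=False)
        assert not post.table["significant"].any()

    def test_lsd_criterion_consistent_with_significance(self, three_groups):
        values, groups = three_groups
        post = fisher_plsd(values, groups)
        for _, row in post.table.iterrows():
            assert row["significant"] == (abs(row["mean_diff"])
                                          > row["lsd"])
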