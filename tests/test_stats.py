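"""Statistical engine: outlier rule, tests, effect sizes, corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triadsim.datasets import STUDY1_APRIORI, STUDY2_APRIORI, worked_examples
from triadsim.stats import (
    GroupSummary,
    anova_oneway,
    bonferroni_family,
    chi_square_independence,
    extreme_outlier_mask,
    gg_epsilon,
    holm_adjust,
    kruskal_wallis,
    mixed_rm_anova,
    t_test_two_sample,
)


class TestOutlierRule:
    def test_single_extreme_value(self):
        # Q1=2, Q3=4, IQR=2 -> upper fence 10: only 100 is excluded
        mask = extreme_outlier_mask([1, 2, 3, 4, 100])
        assert mask.tolist() == [True, True, True, True, False]

    def test_all_equal_none_excluded(self):
        assert extreme_outlier_mask([5, 5, 5, 5, 5]).all()

    def test_sign_flip_symmetry(self):
        values = np.array([-3.0, -1.0, 0.0, 1.0, 3.0, 40.0])
        assert (
            extreme_outlier_mask(values).tolist()
            == extreme_outlier_mask(-values)[::-1].tolist()[::-1]
        )
        # and a symmetric sample keeps the same mask under negation
        sym = np.array([-10.0, -2.0, -1.0, 1.0, 2.0, 10.0])
        assert extreme_outlier_mask(sym).tolist() == extreme_outlier_mask(-sym)[::-1].tolist()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            extreme_outlier_mask([1.0, 2.0, 3.0])

    def test_nan_handling(self):
        mask = extreme_outlier_mask([1, 2, np.nan, 3, 4, 100])
        assert not mask[2] and not mask[5]


class TestChiSquare:
    def test_three_group_sex_table(self):
        # 2x3 table -> no continuity correction by default
        table = np.array([[15, 12], [15, 11], [15, 12]])
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(0.03, abs=0.005)
        assert res.df == (2,)
        assert res.p == pytest.approx(0.984, abs=0.001)
        assert res.correction == "none"

    def test_two_group_sex_table_yates(self):
        table = np.array([[33, 29], [22, 16]])
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(0.06, abs=0.005)
        assert res.p == pytest.approx(0.80, abs=0.005)
        assert res.correction == "yates"

    def test_independent_table_zero(self):
        margins = np.outer([30, 20], [3, 7])  # exact independence
        res = chi_square_independence(margins, continuity=False)
        assert res.statistic == pytest.approx(0.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])


class TestTTest:
    def test_printed_age_summaries(self):
        res = t_test_two_sample(STUDY2_APRIORI["age"])
        assert res.effect == pytest.approx(-0.36, abs=0.005)
        assert res.p == pytest.approx(0.08, abs=0.005)
        assert res.df == (98,)

    def test_identical_groups(self):
        res = t_test_two_sample([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == 0.0
        assert res.effect == 0.0

    def test_raw_equals_summary_path(self, rng):
        a = rng.normal(10, 2, 30)
        b = rng.normal(11, 3, 20)
        raw = t_test_two_sample([a, b])
        summaries = [
            GroupSummary("a", 30, float(a.mean()), float(a.std(ddof=1))),
            GroupSummary("b", 20, float(b.mean()), float(b.std(ddof=1))),
        ]
        summ = t_test_two_sample(summaries)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.effect == pytest.approx(summ.effect, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_degenerate_variance(self):
        equal = t_test_two_sample([[5.0, 5.0], [5.0, 5.0]])
        assert equal.statistic == 0.0 and equal.effect == 0.0
        unequal = t_test_two_sample([[5.0, 5.0], [6.0, 6.0]])
        assert np.isinf(unequal.statistic)


class TestOneWayAnova:
    def test_printed_iq_summaries(self):
        res = anova_oneway(STUDY1_APRIORI["wm_iq"])
        assert res.effect == pytest.approx(0.02, abs=0.005)
        assert res.p == pytest.approx(0.45, abs=0.005)

    def test_printed_alertness_summaries(self):
        res = anova_oneway(STUDY1_APRIORI["alertness"])
        assert res.effect == pytest.approx(0.04, abs=0.005)

    def test_equal_means(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect == pytest.approx(0.0)

    def test_raw_equals_summary_path(self, rng):
        groups = [rng.normal(m, 2, n) for m, n in ((10, 12), (11, 9), (9, 15))]
        raw = anova_oneway(groups)
        summ = anova_oneway(
            [
                GroupSummary(f"g{i}", len(g), float(g.mean()), float(g.std(ddof=1)))
                for i, g in enumerate(groups)
            ]
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        assert raw.effect == pytest.approx(summ.effect, abs=1e-12)


class TestKruskalWallis:
    def test_against_rank_bruteforce(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
        ranks = {v: i + 1 for i, v in enumerate(sorted(sum(groups, [])))}
        n = 9
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2
            for g in groups
        )
        assert res.statistic == pytest.approx(h)
        assert res.effect == pytest.approx((h - 3 + 1) / (9 - 3))

    def test_identical_groups(self):
        res = kruskal_wallis([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert res.statistic == 0.0
        assert res.effect == pytest.approx((0 - 3 + 1) / (9 - 3))

    def test_monotone_relabelling_invariance(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(1, 1, 8)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])  # strictly monotone map
        assert a.statistic == pytest.approx(b.statistic)


class TestMixedAnova:
    @staticmethod
    def _simulate(rng, n_per_group=(15, 15), levels=2, effects=(0.5, 0.3, 0.4)):
        g_off, t_off, i_off = effects
        rows = []
        for gi, n in enumerate(n_per_group):
            for s in range(n):
                base = rng.normal(gi * g_off, 1.0)
                for t in range(levels):
                    rows.append(
                        dict(
                            subject=f"g{gi}s{s}",
                            group=f"g{gi}",
                            time=f"t{t}",
                            y=base + t * t_off + gi * t * i_off + rng.normal(0, 0.5),
                        )
                    )
        return pd.DataFrame(rows)

    @staticmethod
    def _loop_oracle(df):
        """Textbook sums of squares computed with explicit loops."""
        subjects = sorted(df["subject"].unique())
        levels = sorted(df["time"].unique())
        groups = sorted(df["group"].unique())
        y = {
            (r["subject"], r["time"]): r["y"] for _, r in df.iterrows()
        }
        group_of = {s: df[df["subject"] == s]["group"].iloc[0] for s in subjects}
        grand = np.mean([y[(s, t)] for s in subjects for t in levels])
        b = len(levels)
        subj_mean = {s: np.mean([y[(s, t)] for t in levels]) for s in subjects}
        lev_mean = {t: np.mean([y[(s, t)] for s in subjects]) for t in levels}
        grp_mean = {
            g: np.mean([y[(s, t)] for s in subjects if group_of[s] == g for t in levels])
            for g in groups
        }
        cell_mean = {
            (g, t): np.mean([y[(s, t)] for s in subjects if group_of[s] == g])
            for g in groups
            for t in levels
        }
        n_g = {g: sum(1 for s in subjects if group_of[s] == g) for g in groups}
        N = len(subjects)
        ss_group = b * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in groups)
        ss_bs = b * sum((subj_mean[s] - grand) ** 2 for s in subjects)
        ss_err_b = ss_bs - ss_group
        ss_time = N * sum((lev_mean[t] - grand) ** 2 for t in levels)
        ss_int = sum(
            n_g[g] * (cell_mean[(g, t)] - grp_mean[g] - lev_mean[t] + grand) ** 2
            for g in groups
            for t in levels
        )
        ss_ws = sum(
            (y[(s, t)] - subj_mean[s]) ** 2 for s in subjects for t in levels
        )
        ss_err_w = ss_ws - ss_time - ss_int
        a = len(groups)
        f_group = (ss_group / (a - 1)) / (ss_err_b / (N - a))
        f_time = (ss_time / (b - 1)) / (ss_err_w / ((N - a) * (b - 1)))
        f_int = (ss_int / ((a - 1) * (b - 1))) / (ss_err_w / ((N - a) * (b - 1)))
        return f_group, f_time, f_int

    @pytest.mark.parametrize("n_per_group", [(15, 15), (22, 9), (10, 14, 18)])
    def test_agrees_with_loop_oracle(self, rng, n_per_group):
        df = self._simulate(rng, n_per_group=n_per_group)
        res = mixed_rm_anova(df, "subject", "group", "time", "y")
        f_group, f_time, f_int = self._loop_oracle(df)
        assert res["between"].statistic == pytest.approx(f_group, abs=1e-6)
        assert res["within"].statistic == pytest.approx(f_time, abs=1e-6)
        assert res["interaction"].statistic == pytest.approx(f_int, abs=1e-6)

    def test_agrees_with_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self._simulate(rng, n_per_group=(18, 18), levels=3)
        res = mixed_rm_anova(df, "subject", "group", "time", "y")
        aov = pg.mixed_anova(
            data=df, dv="y", within="time", between="group", subject="subject"
        ).set_index("Source")
        assert res["between"].statistic == pytest.approx(aov.loc["group", "F"], abs=1e-8)
        assert res["within"].statistic == pytest.approx(aov.loc["time", "F"], abs=1e-8)
        assert res["interaction"].statistic == pytest.approx(
            aov.loc["Interaction", "F"], abs=1e-8
        )
        assert res["between"].effect == pytest.approx(aov.loc["group", "np2"], abs=1e-8)

    def test_epsilon_matches_pingouin_on_centred_data(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self._simulate(rng, n_per_group=(14, 20), levels=4)
        res = mixed_rm_anova(df, "subject", "group", "time", "y")
        wide = df.pivot_table(index="subject", columns="time", values="y")
        grp = df.groupby("subject")["group"].first()
        centred = wide.sub(wide.groupby(grp).transform("mean"))
        assert res["within"].epsilon_gg == pytest.approx(
            float(pg.epsilon(centred, correction="gg")), abs=1e-9
        )
        assert 1 / 3 <= res["within"].epsilon_gg <= 1.0

    def test_two_levels_epsilon_is_one(self, rng):
        df = self._simulate(rng, levels=2)
        res = mixed_rm_anova(df, "subject", "group", "time", "y")
        assert res["within"].epsilon_gg is None  # sphericity trivial for k=2
        assert res["within"].correction == "none"

    def test_zero_within_change(self):
        rows = []
        for gi, off in enumerate((0.0, 1.0)):
            for s in range(6):
                value = off + s * 0.1
                for t in ("pre", "post"):
                    rows.append(dict(subject=f"g{gi}s{s}", group=gi, time=t, y=value))
        res = mixed_rm_anova(pd.DataFrame(rows), "subject", "group", "time", "y")
        assert res["within"].statistic == pytest.approx(0.0)
        assert res["interaction"].statistic == pytest.approx(0.0)
        assert res["between"].statistic > 0

    def test_listwise_deletion_counts(self, rng):
        df = self._simulate(rng, n_per_group=(10, 10))
        df.loc[df["subject"] == "g0s0", "y"] = np.nan
        res = mixed_rm_anova(df, "subject", "group", "time", "y")
        assert res["n_dropped"] == 1
        assert res["n_used"] == 19
        assert res["between"].df == (1, 17)


class TestCorrections:
    def test_holm_stepdown_example(self):
        adjusted = holm_adjust([0.01, 0.04, 0.03])
        assert adjusted == pytest.approx([0.03, 0.06, 0.06])

    def test_holm_single(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_bonferroni_examples(self):
        assert bonferroni_family([0.013], 3) == pytest.approx([0.039])
        assert bonferroni_family([0.5], 4) == pytest.approx([1.0])
        assert bonferroni_family([0.2, 0.4], 2) == pytest.approx([0.4, 0.8])

    def test_bonferroni_family_too_small(self):
        with pytest.raises(ValueError):
            bonferroni_family([0.1, 0.2, 0.3], 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_holm_dominance_and_monotonicity(self, p):
        adjusted = holm_adjust(p)
        p = np.asarray(p)
        assert np.all(adjusted >= p - 1e-15)
        assert np.all(adjusted <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_holm_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 10))
            mine = holm_adjust(p)
            theirs = sm.multipletests(p, method="holm")[1]
            assert mine == pytest.approx(theirs, abs=1e-12)


class TestWorkedExamples:
    def test_all_printed_values_reproduced(self):
        results = worked_examples()
        assert results["sex_chi2_study1"].statistic == pytest.approx(0.03, abs=0.005)
        assert results["sex_chi2_study2"].statistic == pytest.approx(0.06, abs=0.005)
        assert results["wm_iq_partial_eta2"].effect == pytest.approx(0.02, abs=0.005)
        assert results["alertness_partial_eta2"].effect == pytest.approx(0.04, abs=0.005)
        assert results["age_cohen_d_study2"].effect == pytest.approx(-0.36, abs=0.005)
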