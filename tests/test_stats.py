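"""Group statistics: Shapiro-Wilk screening, one-way ANOVA, Tukey-Kramer."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from thztdd.stats import (
    GroupSummary,
    anova_oneway,
    run_group_comparison,
    shapiro_wilk,
    tukey_kramer,
)


def groups_from(*arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return [GroupSummary(l, np.asarray(a, float)) for l, a in zip(labels, arrays)]


class TestShapiroWilk:
    def test_statistic_bounded(self):
        rng = np.random.default_rng(0)
        w, _ = shapiro_wilk(rng.normal(size=20))
        assert 0.0 < w <= 1.0

    def test_exact_normal_quantiles_score_high(self):
        # n=10 sample placed exactly at normal quantiles: as normal as a
        # sample of this size can look
        q = sps.norm.ppf((np.arange(10) + 0.5) / 10)
        w, p = shapiro_wilk(q)
        assert w > 0.98
        assert p > 0.5

    def test_bimodal_sample_rejected(self):
        values = np.array([0.0] * 5 + [100.0] * 5)
        values += np.linspace(0, 0.01, 10)  # break exact ties
        _, p = shapiro_wilk(values)
        assert p < 0.05

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(51, dtype=float))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))


class TestAnova:
    def test_hand_computed_worked_example(self):
        # groups {1,2,3}, {2,3,4}, {3,4,5}: grand mean 3, SS_between =
        # 3*(1+0+1) = 6, SS_within = 2+2+2 = 6, F = (6/2)/(6/6) = 3
        res = anova_oneway(groups_from([1, 2, 3], [2, 3, 4], [3, 4, 5]))
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p_value == pytest.approx(sps.f.sf(3.0, 2, 6))

    def test_equal_means_give_zero_f(self):
        base = [1.0, 2.0, 3.0, 4.0]
        res = anova_oneway(
            groups_from(base, base[::-1], [2.0, 1.0, 4.0, 3.0])
        )
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(2)
        arrays = [rng.normal(size=8) for _ in range(4)]
        f0 = anova_oneway(groups_from(*arrays)).F
        f1 = anova_oneway(groups_from(*[a + 17.3 for a in arrays])).F
        assert f1 == pytest.approx(f0)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(3)
        arrays = [rng.normal(loc=i * 0.3, size=10) for i in range(5)]
        res = anova_oneway(groups_from(*arrays))
        ref = sps.f_oneway(*arrays)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway(groups_from([1.0, 1.0], [2.0, 2.0]))


class TestTukeyKramer:
    def test_identical_groups_nothing_significant(self):
        base = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = tukey_kramer(
            groups_from(base, list(reversed(base)), base)
        )
        assert not any(p.significant for p in res.pairs)
        assert len(res.pairs) == 3

    def test_two_groups_match_pooled_t_test(self):
        # q_{alpha,2,df} = sqrt(2) t_{alpha/2,df}, so the Tukey decision for
        # two groups coincides with the two-sample pooled t-test
        df = 18
        q = tukey_kramer(
            groups_from(np.arange(10.0), np.arange(10.0) + 0.5)
        ).q_critical
        t = sps.t.ppf(1 - 0.025, df)
        assert q == pytest.approx(np.sqrt(2) * t, rel=1e-6)

        rng = np.random.default_rng(4)
        for shift in (0.0, 0.5, 1.5):
            a, b = rng.normal(size=10), rng.normal(loc=shift, size=10)
            tk = tukey_kramer(groups_from(a, b))
            _, p = sps.ttest_ind(a, b)
            assert tk.pairs[0].significant == (p < 0.05)

    def test_agrees_with_statsmodels_on_unbalanced_data(self):
        rng = np.random.default_rng(5)
        sizes = (8, 12, 10, 9)
        arrays = [
            rng.normal(loc=i * 0.6, size=n) for i, n in enumerate(sizes)
        ]
        tk = tukey_kramer(groups_from(*arrays))
        data = np.concatenate(arrays)
        labels = np.concatenate(
            [[f"g{i}"] * n for i, n in enumerate(sizes)]
        )
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        got = {
            frozenset((p.group_a, p.group_b)): p.significant
            for p in tk.pairs
        }
        for (a, b), rej in zip(
            [(r[0], r[1]) for r in ref.summary().data[1:]], ref.reject
        ):
            assert got[frozenset((str(a), str(b)))] == bool(rej)
        assert tk.msd is None  # unbalanced design has no common MSD

    def test_balanced_design_reports_common_msd(self):
        rng = np.random.default_rng(6)
        arrays = [rng.normal(size=10) for _ in range(5)]
        tk = tukey_kramer(groups_from(*arrays))
        expected = tk.q_critical * np.sqrt(tk.ms_within / 10)
        assert tk.msd == pytest.approx(expected)
        for p in tk.pairs:
            assert p.threshold == pytest.approx(tk.msd)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer(groups_from([1.0, 2.0], [3.0, 4.0]), alpha=1.5)

    def test_scale_and_shift_leave_decisions_unchanged(self):
        rng = np.random.default_rng(7)
        arrays = [rng.normal(loc=i, size=6) for i in range(3)]
        base = tukey_kramer(groups_from(*arrays))
        moved = tukey_kramer(
            groups_from(*[3.0 * a - 11.0 for a in arrays])
        )
        for p, q in zip(base.pairs, moved.pairs):
            assert p.significant == q.significant


class TestRunGroupComparison:
    def test_assembles_full_battery(self):
        rng = np.random.default_rng(8)
        groups = groups_from(
            *[rng.normal(loc=i * 0.8, size=10) for i in range(5)],
            labels=["Control", "NT", "PT", "NN", "MN"],
        )
        report = run_group_comparison(groups)
        assert set(report.shapiro) == {"Control", "NT", "PT", "NN", "MN"}
        assert report.anova.df_between == 4
        assert report.anova.df_within == 45
        assert len(report.tukey.pairs) == 10
        d = report.to_dict()
        assert {"shapiro", "anova", "tukey", "isolated_groups"} <= set(d)

    def test_normality_warning_flagged_not_fatal(self):
        rng = np.random.default_rng(9)
        skewed = np.exp(rng.normal(size=12)) * 100  # clearly non-normal
        groups = groups_from(rng.normal(size=12), skewed)
        report = run_group_comparison(groups)
        assert "g1" in report.normality_warning
        assert report.anova.F >= 0  # battery still ran

    def test_power_increases_with_effect_size(self):
        # frequency of "one group significantly different from all others"
        # grows strictly with that group's effect size
        rng = np.random.default_rng(11)
        rates = []
        for effect in (0.5, 1.0, 2.0):
            hits = 0
            for _ in range(200):
                arrays = [rng.normal(size=10) for _ in range(4)]
                arrays.append(rng.normal(loc=effect, size=10))
                report = run_group_comparison(groups_from(*arrays))
                if "g4" in report.isolated_groups():
                    hits += 1
            rates.append(hits / 200)
        assert rates[0] < rates[1] < rates[2]

    def test_isolated_group_detection(self):
        # one group far from three tightly clustered ones: only it is
        # significantly different from every other group
        rng = np.random.default_rng(10)
        tight = [rng.normal(scale=0.1, size=10) for _ in range(3)]
        far = rng.normal(loc=5.0, scale=0.1, size=10)
        groups = groups_from(*tight, far)
        report = run_group_comparison(groups)
        assert report.isolated_groups() == ("g3",)
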