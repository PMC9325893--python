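"""Statistical battery: ANOVA/Tukey, Kruskal-Wallis/Dunn, normality,
regression, limb averaging, and the cohort-simulation harness."""

import numpy as np
import pytest
from scipy import stats as sps

from plvquant.datatypes import GroupSample
from plvquant.stats import (
    kruskal_dunn,
    limb_aggregate,
    linear_regression,
    one_way_anova_tukey,
    shapiro_wilk,
    significance_harness,
    two_way_anova,
)


def _groups(*arrays, names=None):
    names = names or [f"g{i}" for i in range(len(arrays))]
    return [GroupSample(n, np.asarray(a, float)) for n, a in zip(names, arrays)]


class TestOneWayAnovaTukey:
    def test_identical_groups_give_p_one(self):
        r = one_way_anova_tukey(_groups([1, 2, 3], [1, 2, 3]))
        # identical data in both groups: no between-group effect
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_all_constant_equal(self):
        r = one_way_anova_tukey(_groups([5, 5, 5], [5, 5, 5]))
        assert (r.statistic, r.p_value) == (0.0, 1.0)
        assert r.pairwise[0][2] == 1.0

    def test_degenerate_separation(self):
        r = one_way_anova_tukey(_groups([0, 0, 0], [10, 10, 10]))
        assert r.p_value < 1e-10
        assert r.pairwise[0][2] < 1e-10

    def test_f_matches_scipy(self, rng):
        vals = [rng.normal(i, 1.0, size=9) for i in range(3)]
        r = one_way_anova_tukey(_groups(*vals))
        f, p = sps.f_oneway(*vals)
        assert r.statistic == pytest.approx(f, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-10)

    def test_tukey_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = [rng.normal(m, 2.0, size=n) for m, n in ((0, 12), (1.5, 8), (1, 10))]
        r = one_way_anova_tukey(_groups(*vals))
        data = np.concatenate(vals)
        labels = np.repeat(["g0", "g1", "g2"], [12, 8, 10])
        sm = pairwise_tukeyhsd(data, labels)
        rows = sm.summary().data[1:]  # (group1, group2, meandiff, ..., p-adj, ...)
        for a, b, p in r.pairwise:
            sm_pair = [
                pv
                for row, pv in zip(rows, sm.pvalues)
                if {str(row[0]), str(row[1])} == {a, b}
            ][0]
            assert p == pytest.approx(sm_pair, abs=1e-4)

    def test_tukey_conservative_vs_t_test(self, rng):
        vals = [rng.normal(i * 0.5, 1.0, size=10) for i in range(3)]
        r = one_way_anova_tukey(_groups(*vals))
        for (a, b, p), (i, j) in zip(r.pairwise, [(0, 1), (0, 2), (1, 2)]):
            t_p = sps.ttest_ind(vals[i], vals[j]).pvalue
            assert p >= t_p - 1e-12

    def test_relabeling_invariance(self, rng):
        vals = [rng.normal(i, 1.0, size=8) for i in range(3)]
        r1 = one_way_anova_tukey(_groups(*vals, names=["a", "b", "c"]))
        r2 = one_way_anova_tukey(
            _groups(vals[2], vals[0], vals[1], names=["c", "a", "b"])
        )
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.pair_p("a", "b") == pytest.approx(r2.pair_p("a", "b"))

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 over 2000 simulated cohorts."""
        rng = np.random.default_rng(2024)
        rej = 0
        reps = 2000
        for _ in range(reps):
            vals = [rng.normal(10.0, 2.0, size=8) for _ in range(3)]
            rej += one_way_anova_tukey(_groups(*vals), pairwise=False).p_value < 0.05
        assert 0.04 <= rej / reps <= 0.06


class TestTwoWayAnova:
    def test_single_level_factor_rejected(self, rng):
        y = rng.normal(size=8)
        with pytest.raises(ValueError):
            two_way_anova(y, np.repeat(["x"], 8), np.tile(["u", "v"], 4))

    def test_additive_noiseless_interaction_ss_zero(self):
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        effects = {"a1": 0.0, "a2": 5.0}
        beff = {"b1": 0.0, "b2": 2.0}
        jitter = np.tile([-0.1, 0.0, 0.1], 4)  # within-cell spread only
        y = np.array([effects[x] for x in a]) + np.array(
            [beff[x] for x in b]
        ) + jitter
        r = two_way_anova(y, a, b)
        assert r.details["ss_interaction"] == pytest.approx(0.0, abs=1e-9)

    def test_balanced_layout_matches_hand_computation(self, rng):
        # balanced 2x2, n=4/cell: Type II equals the classical Type I SS
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        y = rng.normal(0, 1, size=16) + (a == "a2") * 1.5 + (b == "b2") * 0.7
        r = two_way_anova(y, a, b)
        grand = y.mean()
        ss_a = sum(
            8 * (y[a == lv].mean() - grand) ** 2 for lv in ("a1", "a2")
        )
        ss_b = sum(
            8 * (y[b == lv].mean() - grand) ** 2 for lv in ("b1", "b2")
        )
        cell_means = {
            (la, lb): y[(a == la) & (b == lb)].mean()
            for la in ("a1", "a2")
            for lb in ("b1", "b2")
        }
        ss_cells = sum(
            4 * (m - grand) ** 2 for m in cell_means.values()
        )
        ss_int = ss_cells - ss_a - ss_b
        assert r.details["ss_a"] == pytest.approx(ss_a, rel=1e-10)
        assert r.details["ss_b"] == pytest.approx(ss_b, rel=1e-10)
        assert r.details["ss_interaction"] == pytest.approx(ss_int, rel=1e-8)

    def test_cell_tukey_present(self, rng):
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        y = rng.normal(size=12)
        r = two_way_anova(y, a, b)
        cell_pairs = [t for t in r.pairwise if "|" in t[0]]
        assert len(cell_pairs) == 6  # C(4,2) cell-mean comparisons


class TestKruskalDunn:
    def test_identical_groups(self):
        r = kruskal_dunn(_groups([4, 4], [4, 4, 4]))
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_hand_rank_oracle(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2, 5, 8
        # H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) = 7.2
        r = kruskal_dunn(_groups([1, 2, 3], [4, 5, 6], [7, 8, 9]))
        assert r.statistic == pytest.approx(7.2)

    def test_dunn_matches_brute_force_formula(self, rng):
        vals = [rng.normal(i, 1.0, size=n) for i, n in ((0, 6), (1, 8), (2, 5))]
        r = kruskal_dunn(_groups(*vals))
        allv = np.concatenate(vals)
        ranks = sps.rankdata(allv)
        n_tot = allv.size
        bounds = np.cumsum([0, 6, 8, 5])
        mr = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(3)]
        ties = [c for _, c in zip(*np.unique(allv, return_counts=True))][1]
        var = n_tot * (n_tot + 1) / 12.0  # no ties in continuous draws
        for (a, b, p), (i, j) in zip(r.pairwise, [(0, 1), (0, 2), (1, 2)]):
            z = abs(mr[i] - mr[j]) / np.sqrt(
                var * (1 / len(vals[i]) + 1 / len(vals[j]))
            )
            expect = min(1.0, 2 * sps.norm.sf(z) * 3)
            assert p == pytest.approx(expect, rel=1e-10)

    def test_exact_small_sample_matches_permutation_mc(self, rng):
        from plvquant.stats import _kw_h

        vals = [np.array([1.0, 5.0, 2.0]), np.array([3.0, 8.0]),
                np.array([9.0, 4.0])]
        r = kruskal_dunn(_groups(*vals))  # n=7 -> exact enumeration
        ranks = sps.rankdata(np.concatenate(vals))
        sizes = [3, 2, 2]
        h_obs = _kw_h(ranks, sizes, 1.0)
        mc = np.mean(
            [
                _kw_h(rng.permutation(ranks), sizes, 1.0) >= h_obs - 1e-12
                for _ in range(20000)
            ]
        )
        assert r.p_value == pytest.approx(mc, abs=0.02)

    def test_asymptotic_matches_scipy_large_n(self, rng):
        vals = [rng.normal(i, 1, size=15) for i in range(3)]
        r = kruskal_dunn(_groups(*vals))
        h, p = sps.kruskal(*vals)
        assert r.statistic == pytest.approx(h, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-10)

    def test_relabeling_invariance(self, rng):
        vals = [rng.normal(i, 1, size=12) for i in range(3)]
        r1 = kruskal_dunn(_groups(*vals, names=["a", "b", "c"]))
        r2 = kruskal_dunn(_groups(vals[1], vals[2], vals[0],
                                  names=["b", "c", "a"]))
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.pair_p("b", "c") == pytest.approx(r2.pair_p("b", "c"))


class TestShapiroWilk:
    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))

    def test_null_p_roughly_uniform(self):
        ps = [
            shapiro_wilk(np.random.default_rng(s).normal(size=25)).p_value
            for s in range(300)
        ]
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= frac <= 0.09
        assert 0.3 <= np.median(ps) <= 0.7

    def test_power_against_right_skew(self):
        ps = [
            shapiro_wilk(
                np.random.default_rng(s).exponential(size=50)
            ).p_value
            for s in range(20)
        ]
        assert np.median(ps) < 0.05


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = linear_regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_independent_y_near_zero_r2(self):
        rng = np.random.default_rng(3)
        r = linear_regression(np.arange(2000.0), rng.normal(size=2000))
        assert r.r_squared < 0.01

    def test_normal_equation_oracle(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 1.3 * x + rng.normal(0, 2, 40)
        r = linear_regression(x, y)
        xc = x - x.mean()
        slope = (xc * (y - y.mean())).sum() / (xc**2).sum()
        intercept = y.mean() - slope * x.mean()
        resid = y - slope * x - intercept
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r.slope == pytest.approx(slope, rel=1e-10)
        assert r.intercept == pytest.approx(intercept, rel=1e-10)
        assert r.r_squared == pytest.approx(r2, rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression(np.ones(5), np.arange(5.0))


class TestLimbAggregate:
    def test_pairs_and_singletons(self):
        out = limb_aggregate(np.array([2.0, 4.0, 5.0]),
                             np.array(["L1", "L1", "L2"]))
        assert out["L1"] == 3.0
        assert out["L2"] == 5.0

    def test_randomized_fixture_matches_manual_groupby(self, rng):
        limbs = np.repeat([f"L{i}" for i in range(10)], 2)
        vals = rng.normal(size=20)
        out = limb_aggregate(vals, limbs)
        manual = {}
        for limb, v in zip(limbs, vals):
            manual.setdefault(limb, []).append(v)
        for limb, vs in manual.items():
            assert out[limb] == pytest.approx(np.mean(vs))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            limb_aggregate(np.arange(3.0), np.array(["L1", "L1", "L1"]))


class TestSignificanceHarness:
    def test_zero_effect_spec_has_uniform_median_p(self):
        df = significance_harness(
            [("a", 10.0, 2.0, 12), ("b", 10.0, 2.0, 12)],
            "one_way_anova_tukey",
            n_reps=300,
            seed=5,
        )
        p = df["median_adjusted_p"].iloc[0]
        assert 0.3 <= p <= 0.7
        assert df["rejection_fraction"].iloc[0] <= 0.12

    def test_separated_degenerate_spec(self):
        df = significance_harness(
            [("a", 0.0, 0.0, 5), ("b", 10.0, 0.0, 5)],
            "one_way_anova_tukey",
            n_reps=100,
            seed=2,
        )
        assert df["median_adjusted_p"].iloc[0] < 1e-10
        assert df["rejection_fraction"].iloc[0] == 1.0

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            significance_harness([("a", 1, 1, 5)], "mann_whitney", 100, 0)
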