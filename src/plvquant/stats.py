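"""Group-comparison statistics and the cohort-simulation harness.

Implements the statistical battery applied to the vessel measurements:
one-/two-way ANOVA with Tukey's multiple comparisons, Kruskal-Wallis
with Dunn's multiple comparisons (Bonferroni family), Shapiro-Wilk
normality, ordinary least-squares regression, per-limb averaging of the
two vessels of each hindlimb, and a harness that repeatedly simulates
cohorts from printed summary statistics and summarizes the resulting
adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GroupSample
from .synthgen import gen_cohort

__all__ = [
    "TestResult",
    "RegressionResult",
    "one_way_anova_tukey",
    "two_way_anova",
    "kruskal_dunn",
    "shapiro_wilk",
    "linear_regression",
    "limb_aggregate",
    "significance_harness",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def pair_p(self, a: str, b: str) -> float:
        for ga, gb, p in self.pairwise:
            if {ga, gb} == {a, b}:
                return p
        raise KeyError(f"no pairwise comparison {a} vs {b}")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _as_arrays(groups: list[GroupSample]) -> tuple[list[str], list[np.ndarray]]:
    names = [g.group for g in groups]
    vals = [np.asarray(g.values, dtype=float) for g in groups]
    return names, vals


def one_way_anova_tukey(
    groups: list[GroupSample], pairwise: bool = True
) -> TestResult:
    """Classical one-way ANOVA F-test with Tukey-Kramer adjusted pairs.

    Degenerate inputs are resolved explicitly: all observations
    identical gives F = 0, p = 1; zero within-group variance with
    separated group means gives p below 1e-10. ``pairwise=False`` skips
    the Tukey comparisons (the studentized-range tail is costly) when
    only the omnibus F is needed.
    """
    names, vals = _as_arrays(groups)
    if len(vals) < 2 or any(v.size < 2 for v in vals):
        raise ValueError("need >= 2 groups with n >= 2 each")
    allv = np.concatenate(vals)
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    df_b = len(vals) - 1
    df_w = allv.size - len(vals)

    if ss_within <= 0 and ss_between <= 0:
        f_stat, p = 0.0, 1.0
    elif ss_within <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))

    pairs = _tukey_pairs(names, vals, ss_within, df_w) if pairwise else []
    return TestResult("one_way_anova_tukey", float(f_stat), p, pairs)


def _tukey_pairs(
    names: list[str], vals: list[np.ndarray], ss_within: float, df_w: int
) -> list[tuple[str, str, float]]:
    """Tukey-Kramer adjusted p per pair via the studentized range."""
    mse = ss_within / df_w if df_w > 0 else 0.0
    out = []
    for i, j in combinations(range(len(vals)), 2):
        vi, vj = vals[i], vals[j]
        diff = abs(vi.mean() - vj.mean())
        if mse <= 0:
            p = 1.0 if diff == 0 else min(1e-12, np.finfo(float).tiny * 8)
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
            q = diff / se
            p = float(sps.studentized_range.sf(q, len(vals), df_w))
        out.append((names[i], names[j], min(max(p, 0.0), 1.0)))
    return out


def two_way_anova(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> TestResult:
    """Two-factor ANOVA with Type-II sums of squares; Tukey on cell means.

    The headline (statistic, p) is the interaction test when it is
    estimable, otherwise the factor-A main effect. Main-effect and
    interaction p-values are carried in the pairwise list as
    ("factor_a", "", p) / ("factor_b", "", p) / ("interaction", "", p),
    followed by Tukey-adjusted comparisons over the A x B cell means
    (labelled "a|b").
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    values = np.asarray(values, dtype=float)
    a = np.asarray(factor_a).astype(str)
    b = np.asarray(factor_b).astype(str)
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise ValueError("each factor needs >= 2 levels")
    df = pd.DataFrame({"y": values, "a": a, "b": b})
    n_cells = df.groupby(["a", "b"], observed=True).size()
    formula = "y ~ C(a) * C(b)" if (n_cells > 1).all() else "y ~ C(a) + C(b)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    pairwise: list[tuple[str, str, float]] = [
        ("factor_a", "", float(table.loc["C(a)", "PR(>F)"])),
        ("factor_b", "", float(table.loc["C(b)", "PR(>F)"])),
    ]
    details = {
        "ss_a": float(table.loc["C(a)", "sum_sq"]),
        "ss_b": float(table.loc["C(b)", "sum_sq"]),
        "ss_residual": float(table.loc["Residual", "sum_sq"]),
        "f_a": float(table.loc["C(a)", "F"]),
        "f_b": float(table.loc["C(b)", "F"]),
    }
    if "C(a):C(b)" in table.index:
        stat = float(table.loc["C(a):C(b)", "F"])
        p = float(table.loc["C(a):C(b)", "PR(>F)"])
        pairwise.append(("interaction", "", p))
        details["ss_interaction"] = float(table.loc["C(a):C(b)", "sum_sq"])
    else:
        stat = float(table.loc["C(a)", "F"])
        p = float(table.loc["C(a)", "PR(>F)"])

    cells = {
        f"{ka}|{kb}": g["y"].to_numpy()
        for (ka, kb), g in df.groupby(["a", "b"], observed=True)
    }
    cell_groups = [GroupSample(k, v) for k, v in cells.items()]
    if all(v.size >= 2 for v in cells.values()):
        pairwise += one_way_anova_tukey(cell_groups).pairwise
    return TestResult("two_way_anova", stat, p, pairwise, details)


def _kw_h(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled ranks in group order."""
    n_tot = ranks.size
    idx = np.cumsum([0] + sizes)
    h = 12.0 / (n_tot * (n_tot + 1)) * sum(
        sizes[i] * (ranks[idx[i] : idx[i + 1]].mean() - (n_tot + 1) / 2.0) ** 2
        for i in range(len(sizes))
    )
    return h / tie_factor if tie_factor > 0 else 0.0


def _kw_exact_p(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> float:
    """Exact permutation p for H by enumerating group assignments."""
    from itertools import combinations as comb

    h_obs = _kw_h(ranks, sizes, tie_factor)
    n_tot = ranks.size

    def recurse(avail: tuple[int, ...], gi: int) -> tuple[int, int]:
        if gi == len(sizes) - 1:
            perm = np.concatenate([parts[g] for g in range(gi)] + [ranks[list(avail)]])
            return (1, int(_kw_h(perm, sizes, tie_factor) >= h_obs - 1e-12))
        total = hits = 0
        for pick in comb(range(len(avail)), sizes[gi]):
            chosen = [avail[i] for i in pick]
            parts[gi] = ranks[chosen]
            rest = tuple(a for i, a in enumerate(avail) if i not in set(pick))
            t, h = recurse(rest, gi + 1)
            total += t
            hits += h
        return total, hits

    parts: dict[int, np.ndarray] = {}
    total, hits = recurse(tuple(range(n_tot)), 0)
    return hits / total


def kruskal_dunn(groups: list[GroupSample], p_method: str = "auto") -> TestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise z-tests.

    The global p is asymptotic (chi-square) for larger samples; for
    total n <= 10 (or ``p_method='exact'``) it is the exact permutation
    p over all group assignments, where the chi-square approximation is
    unreliable. Dunn (1964): z on mean ranks with the tie-corrected
    variance (N(N+1)/12 - sum(t^3 - t)/(12(N-1))); two-sided normal p
    adjusted by Bonferroni over all k(k-1)/2 comparisons.
    """
    if p_method not in ("auto", "asymptotic", "exact"):
        raise ValueError("p_method must be auto, asymptotic, or exact")
    names, vals = _as_arrays(groups)
    if len(vals) < 2 or any(v.size < 1 for v in vals):
        raise ValueError("need >= 2 nonempty groups")
    allv = np.concatenate(vals)
    if allv.size < 3:
        raise ValueError("need total n >= 3")
    exact = p_method == "exact" or (p_method == "auto" and allv.size <= 10)
    if np.ptp(allv) == 0:
        h_stat, p = 0.0, 1.0
    else:
        pooled_ranks = sps.rankdata(allv)
        sizes_ = [v.size for v in vals]
        _, cnt = np.unique(allv, return_counts=True)
        tie_factor = 1.0 - float((cnt**3 - cnt).sum()) / (
            allv.size**3 - allv.size
        )
        h_stat = _kw_h(pooled_ranks, sizes_, tie_factor)
        if exact:
            p = _kw_exact_p(pooled_ranks, sizes_, tie_factor)
        else:
            p = float(sps.chi2.sf(h_stat, len(vals) - 1))

    ranks = sps.rankdata(allv)
    n_tot = allv.size
    sizes = [v.size for v in vals]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[idx[i] : idx[i + 1]].mean() for i in range(len(vals))
    ]
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_tot - 1)))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    n_pairs = len(vals) * (len(vals) - 1) // 2
    pairwise = []
    for i, j in combinations(range(len(vals)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p_ij = 1.0
        else:
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p_ij = min(1.0, 2.0 * float(sps.norm.sf(z)) * n_pairs)
        pairwise.append((names[i], names[j], p_ij))
    return TestResult("kruskal_dunn", h_stat, p, pairwise)


def shapiro_wilk(values: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("all observations identical: W undefined")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p))


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y ~ x with R^2 and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def limb_aggregate(
    values_per_vessel: np.ndarray, limb_ids: np.ndarray
) -> pd.Series:
    """Per-limb mean of the (one or two) vessels of each hindlimb.

    Limbs normally contribute two vessels; anatomical-variant limbs
    with a single vessel pass through unchanged. Zero or more than two
    vessels per limb is an input error.
    """
    df = pd.DataFrame({"limb": np.asarray(limb_ids), "value": values_per_vessel})
    counts = df.groupby("limb", observed=True).size()
    bad = counts[(counts < 1) | (counts > 2)]
    if len(bad):
        raise ValueError(f"limbs with invalid vessel counts: {dict(bad)}")
    return df.groupby("limb", observed=True)["value"].mean()


def significance_harness(
    cohort_spec: list[tuple[str, float, float, int]],
    test_name: str,
    n_reps: int = 200,
    seed: int = 0,
    truncate_at_zero: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate cohort simulation + test; summarize adjusted pairwise p.

    For each of ``n_reps`` seeded replicates, draws the cohorts from
    their summary statistics and applies the named test
    ("kruskal_dunn" or "one_way_anova_tukey"). Returns one row per
    pairwise comparison with the median adjusted p and the fraction of
    replicates rejecting at ``alpha``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    tests = {
        "kruskal_dunn": kruskal_dunn,
        "one_way_anova_tukey": one_way_anova_tukey,
    }
    if test_name not in tests:
        raise ValueError(f"unknown test {test_name!r}; options: {sorted(tests)}")
    test = tests[test_name]
    child_seeds = np.random.SeedSequence([int(seed), 7]).generate_state(n_reps)

    rows: dict[tuple[str, str], list[float]] = {}
    for s in child_seeds:
        groups = gen_cohort(
            cohort_spec, seed=int(s) % (2**31 - 1), truncate_at_zero=truncate_at_zero
        )
        result = test(groups)
        for a, b, p in result.pairwise:
            rows.setdefault((a, b), []).append(p)
    records = [
        {
            "group_a": a,
            "group_b": b,
            "median_adjusted_p": float(np.median(ps)),
            "rejection_fraction": float(np.mean(np.asarray(ps) < alpha)),
            "n_reps": n_reps,
        }
        for (a, b), ps in rows.items()
    ]
    return pd.DataFrame.from_records(records)
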