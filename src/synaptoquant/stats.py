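"""Group-comparison rules for synaptic count and imaging data.

Count measures from EM profiles are non-normal but mean-centred, so the
default plan is a heteroscedasticity-robust one: a Brown–Forsythe-corrected
one-way ANOVA with Games–Howell post-hoc pairwise tests. Groups containing
exact-zero measurements break the Brown–Forsythe correction, so such
designs fall back to Kruskal–Wallis with Dunn's multiple comparisons; a
two-group design with zeros falls back to Mann–Whitney. The selection
logic records which rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestPlan",
    "StatResult",
    "select_method",
    "run_comparison",
    "brown_forsythe_anova",
    "games_howell",
    "dunn_test",
]

ALPHA = 0.05


@dataclass
class TestPlan:
    omnibus: str  # brown_forsythe_anova | kruskal_wallis | welch_t | mann_whitney
    posthoc: str  # games_howell | dunn | none
    selection_rationale: str
    pairs: list[tuple[str, str]] | None = None
    dunn_adjust: str = "holm"


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame  # group1, group2, statistic, p_unadjusted, p_adjusted
    group_summaries: pd.DataFrame  # group, n, mean, sem
    alpha: float
    selection_rationale: str


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n={len(v)} < 2")
        out[name] = v
    return out


def select_method(
    groups: dict[str, np.ndarray],
    *,
    pairs: list[tuple[str, str]] | None = None,
    zero_rule: str = "any_zero",
    dunn_adjust: str = "holm",
) -> TestPlan:
    """Choose the comparison plan from the group count and zero content.

    ``zero_rule='any_zero'`` (default) switches to the rank-based fallback
    when any group contains at least one exact zero; ``'all_zero_group'``
    only when an entire group is zero.
    """
    g = _validate_groups(groups)
    if zero_rule == "any_zero":
        has_zero = any(np.any(v == 0) for v in g.values())
    elif zero_rule == "all_zero_group":
        has_zero = any(np.all(v == 0) for v in g.values())
    else:
        raise ValueError(f"unknown zero_rule {zero_rule!r}")
    k = len(g)
    if k > 2 and not has_zero:
        return TestPlan("brown_forsythe_anova", "games_howell",
                        f"{k} groups, no zero measurements -> Brown-Forsythe ANOVA + Games-Howell",
                        pairs, dunn_adjust)
    if k > 2:
        return TestPlan("kruskal_wallis", "dunn",
                        f"{k} groups with zero measurements -> Kruskal-Wallis + Dunn",
                        pairs, dunn_adjust)
    if not has_zero:
        return TestPlan("welch_t", "games_howell",
                        "2 groups, no zero measurements -> t test with Brown-Forsythe "
                        "correction and Games-Howell",
                        pairs, dunn_adjust)
    return TestPlan("mann_whitney", "none",
                    "2 groups with zero measurements -> Mann-Whitney", pairs, dunn_adjust)


def brown_forsythe_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Brown–Forsythe one-way ANOVA robust to unequal variances.

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with Satterthwaite
    denominator degrees of freedom. Returns (F, df1, df2, p).
    """
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    N = n.sum()
    grand = np.sum(n * m) / N
    denom_terms = (1.0 - n / N) * s2
    denom = denom_terms.sum()
    if denom <= 0:
        raise ValueError("degenerate variance in all groups")
    F = float(np.sum(n * (m - grand) ** 2) / denom)
    c = denom_terms / denom
    df1 = float(len(groups) - 1)
    df2 = float(1.0 / np.sum(c**2 / (n - 1)))
    p = float(sps.f.sf(F, df1, df2))
    return F, df1, df2, p


def games_howell(groups: dict[str, np.ndarray],
                 pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Games–Howell pairwise comparisons.

    Welch t statistics with Satterthwaite degrees of freedom, referred to
    the studentized-range distribution with the total group count k, so
    the returned p values are family-adjusted.
    """
    names = list(groups)
    k = len(names)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for a, b in pairs:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
        se2 = vx + vy
        if se2 <= 0:
            raise ValueError(f"degenerate variance in pair ({a!r}, {b!r})")
        t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
        df = se2**2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        rows.append({"group1": a, "group2": b, "statistic": float(t),
                     "p_unadjusted": p, "p_adjusted": min(p, 1.0)})
    return pd.DataFrame(rows)


def dunn_test(groups: dict[str, np.ndarray],
              pairs: list[tuple[str, str]] | None = None,
              adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal–Wallis.

    z statistics on mean ranks with tie correction; multiplicity adjusted
    over the requested pairs (Holm by default; 'bonferroni' and 'sidak'
    selectable).
    """
    names = list(groups)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    all_vals = np.concatenate([np.asarray(groups[n], float) for n in names])
    ranks = sps.rankdata(all_vals)
    N = len(all_vals)
    rank_by_group, i = {}, 0
    for n in names:
        cnt = len(groups[n])
        rank_by_group[n] = ranks[i:i + cnt]
        i += cnt
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in pairs:
        na, nb = len(rank_by_group[a]), len(rank_by_group[b])
        z = (np.mean(rank_by_group[a]) - np.mean(rank_by_group[b])) / np.sqrt(
            var_base * (1.0 / na + 1.0 / nb)
        )
        p = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append({"group1": a, "group2": b, "statistic": float(z), "p_unadjusted": min(p, 1.0)})
    df = pd.DataFrame(rows)
    method = {"holm": "holm", "bonferroni": "bonferroni", "sidak": "sidak"}[adjust]
    df["p_adjusted"] = multipletests(df["p_unadjusted"], method=method)[1]
    return df


def _summaries(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, v in groups.items():
        v = np.asarray(v, float)
        rows.append({"group": name, "n": len(v), "mean": float(np.mean(v)),
                     "sem": float(np.std(v, ddof=1) / np.sqrt(len(v)))})
    return pd.DataFrame(rows)


def run_comparison(groups: dict[str, np.ndarray], plan: TestPlan | None = None,
                   *, alpha: float = ALPHA) -> StatResult:
    """Execute a comparison plan (from :func:`select_method` by default)."""
    g = _validate_groups(groups)
    if plan is None:
        plan = select_method(g)
    empty = pd.DataFrame(columns=["group1", "group2", "statistic", "p_unadjusted", "p_adjusted"])

    if plan.omnibus == "brown_forsythe_anova":
        F, _, _, p = brown_forsythe_anova(list(g.values()))
        post = games_howell(g, plan.pairs)
        return StatResult("Brown-Forsythe ANOVA + Games-Howell", F, p, post,
                          _summaries(g), alpha, plan.selection_rationale)

    if plan.omnibus == "kruskal_wallis":
        H, p = sps.kruskal(*g.values())
        post = dunn_test(g, plan.pairs, adjust=plan.dunn_adjust)
        return StatResult("Kruskal-Wallis + Dunn", float(H), float(p), post,
                          _summaries(g), alpha, plan.selection_rationale)

    if plan.omnibus == "welch_t":
        # two-group Brown-Forsythe/Games-Howell reduces to the Welch t test
        F, _, _, p = brown_forsythe_anova(list(g.values()))
        post = games_howell(g, plan.pairs)
        return StatResult("Welch t (Brown-Forsythe) + Games-Howell",
                          float(post["statistic"].iloc[0]), p, post,
                          _summaries(g), alpha, plan.selection_rationale)

    if plan.omnibus == "mann_whitney":
        names = list(g)
        x, y = g[names[0]], g[names[1]]
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        post = pd.DataFrame([{"group1": names[0], "group2": names[1],
                              "statistic": float(res.statistic),
                              "p_unadjusted": float(res.pvalue),
                              "p_adjusted": float(res.pvalue)}])
        return StatResult("Mann-Whitney U", float(res.statistic), float(res.pvalue),
                          post, _summaries(g), alpha, plan.selection_rationale)

    raise ValueError(f"unknown omnibus {plan.omnibus!r}")
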