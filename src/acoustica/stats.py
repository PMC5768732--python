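"""Between-site statistical battery for per-transect metrics and per-fish sizes.

The routing ladder mirrors common practice for unbalanced, heteroscedastic
ecological survey data: Welch's heteroscedastic one-way ANOVA with Tukey HSD
post-hocs on (optionally log10-transformed) metrics; when transformation does
not rescue normality, a Kruskal–Wallis rank test followed by Dunn's post-hoc
comparisons.  Two-sample contrasts use Welch's t, Mann–Whitney or a two-sample
Kolmogorov–Smirnov test.  Every routing decision (Shapiro–Wilk / Levene gates)
is recorded, because these intermediates are what make a reported test
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonPlan",
    "transform_guard",
    "welch_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_posthoc",
    "two_sample",
    "pearson_ols",
    "percent_difference",
    "route_and_compare",
]


@dataclass
class ComparisonPlan:
    """Declarative description of one between-site comparison."""

    metric: str  # density | biomass | sA | length
    groups: list[str] = dc_field(default_factory=list)
    transform: str = "none"  # none | log10
    test_path: str = "auto"  # auto | anova_tukey | kw_dunn | t_test | mann_whitney | ks
    exclusions: list[str] = dc_field(default_factory=list)  # transect ids (e.g. school outlier)


def transform_guard(values, transform: str = "none"):
    """Elementwise log10 (requiring strictly positive input) or identity.

    Non-positive values under log10 raise with the offending indices listed;
    no silent offsets are applied.
    """
    values = np.asarray(values, dtype=float)
    if transform == "none":
        return values
    if transform == "log10":
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise ValueError(
                f"log10 transform requires positive values; offending indices: {bad.tolist()}"
            )
        return np.log10(values)
    raise ValueError(f"unknown transform {transform!r}")


def welch_anova(groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p) with Satterthwaite-style denominator df.  Weights
    are w_i = n_i/s_i²; with all-equal group values every s_i² = 0 and the
    statistic degenerates to F = 0, p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2 or any(g.size < 2 for g in gs):
        raise ValueError("welch_anova needs >= 2 groups with n >= 2 each")
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.all(v == 0):
        if np.ptp(m) == 0:
            return 0.0, float(k - 1), float("inf"), 1.0
        return float("inf"), float(k - 1), float("inf"), 0.0
    w = n / v
    mw = float(np.sum(w * m) / np.sum(w))
    num = float(np.sum(w * (m - mw) ** 2) / (k - 1))
    tmp = float(np.sum((1.0 - w / np.sum(w)) ** 2 / (n - 1)))
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * tmp
    f = num / den
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * tmp) if tmp > 0 else float("inf")
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def tukey_hsd(groups, labels=None) -> list[dict]:
    """All pairwise Tukey HSD comparisons (studentized-range p-values).

    Returns one record per unordered pair; the table is invariant (up to pair
    relabelling) under permutation of the group order.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("tukey_hsd needs >= 2 groups with n >= 2 each")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    res = sps.tukey_hsd(*gs)
    out = []
    for i, j in combinations(range(len(gs)), 2):
        out.append(
            {
                "a": labels[i],
                "b": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p": float(res.pvalue[i, j]),
            }
        )
    return out


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal–Wallis H with tie correction; returns (H, df, p)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or sum(g.size for g in gs) < 3:
        raise ValueError("kruskal_wallis needs >= 2 groups and total n >= 3")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return 0.0, len(gs) - 1, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), len(gs) - 1, float(p)


def dunn_posthoc(groups, labels=None, adjust: str = "none") -> list[dict]:
    """Dunn's rank-based post-hoc comparisons after Kruskal–Wallis.

    Z_ij = (R̄_i − R̄_j) / sqrt(S²·(1/n_i + 1/n_j)) with the tie-corrected
    pooled variance S² = [N(N+1)/12]·[1 − ΣT/(N³−N)], T = t³−t per tie group.
    ``adjust``: "none" (default) or "bonferroni".
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or sum(g.size for g in gs) < 3:
        raise ValueError("dunn_posthoc needs >= 2 groups and total n >= 3")
    if adjust not in {"none", "bonferroni"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    pooled = np.concatenate(gs)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in gs]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s2 = (n_tot * (n_tot + 1) / 12.0) * (
        1.0 - tie_term / (n_tot**3 - n_tot) if n_tot > 1 else 1.0
    )
    m = len(list(combinations(range(len(gs)), 2)))
    out = []
    for i, j in combinations(range(len(gs)), 2):
        se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out.append({"a": labels[i], "b": labels[j], "z": float(z), "p": float(p)})
    return out


def two_sample(values_a, values_b, mode: str = "t") -> tuple[float, float]:
    """Two-sample contrast: Welch t, Mann–Whitney U (normal approximation with
    tie correction) or two-sample Kolmogorov–Smirnov D."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("two_sample requires non-empty samples")
    if mode == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t mode requires n >= 2 in each sample")
        r = sps.ttest_ind(a, b, equal_var=False)
    elif mode == "mann_whitney":
        r = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    elif mode == "ks":
        r = sps.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(r.statistic), float(r.pvalue)


def pearson_ols(x, y) -> dict:
    """Pearson correlation plus ordinary least squares fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_ols requires equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_ols requires nonzero variance in x and y")
    lr = sps.linregress(x, y)
    r = float(lr.rvalue)
    return {
        "r": r,
        "r_squared": r * r,
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "p": float(lr.pvalue),
    }


def percent_difference(inside_mean: float, outside_mean: float) -> float:
    """Percent elevation of the inside mean over the outside mean."""
    if outside_mean <= 0:
        raise ValueError("outside_mean must be positive")
    return 100.0 * (inside_mean - outside_mean) / outside_mean


def route_and_compare(groups, labels, plan: ComparisonPlan, alpha: float = 0.05) -> dict:
    """Run the transform/fallback ladder on one metric and record the route.

    ``auto`` routing: Shapiro–Wilk per group and Levene across groups on the
    (possibly transformed) data; if normality fails on raw data, retry after
    log10; if it still fails, fall back to Kruskal–Wallis + Dunn on the raw
    values.  Explicit ``test_path`` values bypass the gates.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    report: dict = {"metric": plan.metric, "groups": list(labels), "gates": {}}

    def gates_pass(data):
        sw = [float(sps.shapiro(g).pvalue) if 3 <= g.size <= 5000 else 1.0 for g in data]
        lv = float(sps.levene(*data).pvalue)
        return sw, lv, all(p > alpha for p in sw)

    path = plan.test_path
    transform = plan.transform
    if path == "auto":
        sw, lv, ok = gates_pass(gs)
        report["gates"]["raw"] = {"shapiro_p": sw, "levene_p": lv}
        if ok:
            path, transform = "anova_tukey", "none"
        elif all(g.min() > 0 for g in gs):
            logged = [np.log10(g) for g in gs]
            sw2, lv2, ok2 = gates_pass(logged)
            report["gates"]["log10"] = {"shapiro_p": sw2, "levene_p": lv2}
            if ok2:
                path, transform = "anova_tukey", "log10"
            else:
                path, transform = "kw_dunn", "none"
        else:
            path, transform = "kw_dunn", "none"
    report["route"] = path
    report["transform"] = transform

    data = [transform_guard(g, transform) for g in gs]
    if path == "anova_tukey":
        f, df1, df2, p = welch_anova(data)
        report["omnibus"] = {"test": "welch_anova", "F": f, "df1": df1, "df2": df2, "p": p}
        report["posthoc"] = {"test": "tukey_hsd", "pairs": tukey_hsd(data, labels)}
    elif path == "kw_dunn":
        h, df, p = kruskal_wallis(data)
        report["omnibus"] = {"test": "kruskal_wallis", "H": h, "df": df, "p": p}
        report["posthoc"] = {"test": "dunn", "pairs": dunn_posthoc(data, labels)}
    elif path in {"t_test", "mann_whitney", "ks"}:
        if len(data) != 2:
            raise ValueError(f"{path} requires exactly two groups")
        mode = {"t_test": "t", "mann_whitney": "mann_whitney", "ks": "ks"}[path]
        stat, p = two_sample(data[0], data[1], mode)
        report["omnibus"] = {"test": path, "statistic": stat, "p": p}
    else:
        raise ValueError(f"unknown test_path {path!r}")
    return report
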