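"""Group-comparison statistics.

Covers the complete statistical toolkit of the analysis: two-tailed
unpaired Student's t-test (equal-variance by default, Welch optional),
per-bin Bonferroni correction, Pearson correlation with its t-transform
p-value, one-way ANOVA with Tukey HSD post hoc comparisons via the
studentised-range distribution, and iterative two-sided Grubbs outlier
removal.  Group summaries report mean +/- SEM with SEM = sd/sqrt(n), sd the
n-1 sample standard deviation.  Significance stars follow the convention
* P <= 0.05, ** P <= 0.01, *** P <= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "PairwiseComparison",
    "significance_stars",
    "summarise",
    "unpaired_t_test",
    "bonferroni_per_bin",
    "pearson_correlation",
    "anova_tukey",
    "grubbs_outlier",
]


def significance_stars(p: float) -> str:
    """Star code for a p-value: *** <= 0.001, ** <= 0.01, * <= 0.05, else ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sem: float


def summarise(values: Sequence[float], name: str = "") -> GroupSummary:
    """Mean +/- SEM summary; SEM = sd/sqrt(n) with the n-1 sample sd."""
    v = np.asarray(values, dtype=float)
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupSummary(name, int(v.size), float(v.mean()), sem)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    stars: str


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    groups: tuple[GroupSummary, ...]
    stars: str
    pairwise: tuple[PairwiseComparison, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def unpaired_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    welch: bool = False,
    names: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Two-tailed unpaired t-test (Student equal-variance by default).

    df = n_a + n_b - 2 for the Student form.  Degenerate zero-pooled-
    variance input: equal means give t = 0, p = 1 by convention; unequal
    means are an error (an infinite statistic is not interpretable).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if diff == 0:
                return _t_result(0.0, float(na + nb - 2), 1.0, a, b, names, "welch_t")
            raise ValueError("zero variance with unequal means")
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        label = "welch_t"
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        if pooled == 0:
            if diff == 0:
                return _t_result(0.0, df, 1.0, a, b, names, "student_t")
            raise ValueError("zero pooled variance with unequal means")
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        label = "student_t"
    p = 2.0 * sps.t.sf(abs(t), df)
    return _t_result(float(t), float(df), min(float(p), 1.0), a, b, names, label)


def _t_result(t, df, p, a, b, names, label) -> TestResult:
    return TestResult(
        test=label,
        statistic=t,
        df=df,
        p_value=p,
        groups=(summarise(a, names[0]), summarise(b, names[1])),
        stars=significance_stars(p),
    )


def bonferroni_per_bin(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni correction across bins: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with the two-sided t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((x.size - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = x.size - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(
        test="pearson",
        statistic=r,
        df=float(df),
        p_value=min(p, 1.0),
        groups=(summarise(x, "x"), summarise(y, "y")),
        stars=significance_stars(min(p, 1.0)),
    )


def anova_tukey(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
) -> TestResult:
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    F and its p-value come from the classical between/within decomposition;
    each pair's adjusted p uses the studentised-range distribution with the
    pooled within-group variance (the standard HSD for mildly unbalanced
    designs uses the harmonic pair term sqrt(MSE/2 * (1/na + 1/nb))).
    Identical groups yield F = 0, p = 1.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    k = len(data)
    if k < 3:
        raise ValueError("one-way ANOVA here requires >= 3 groups (use the t-test for 2)")
    if any(d.size < 2 for d in data):
        raise ValueError("every group needs n >= 2")
    ns = np.array([d.size for d in data])
    n_tot = int(ns.sum())
    grand = float(np.concatenate(data).mean())
    ss_between = float(sum(d.size * (d.mean() - grand) ** 2 for d in data))
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_w = k - 1, n_tot - k
    ms_within = ss_within / df_w
    if ms_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
    elif ms_within == 0:
        raise ValueError("zero within-group variance with differing means")
    else:
        f = (ss_between / df_b) / ms_within
        p = float(sps.f.sf(f, df_b, df_w))
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(data[i].mean() - data[j].mean())
            if ms_within == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            p_adj = min(max(p_adj, 0.0), 1.0)
            pairwise.append(
                PairwiseComparison(names[i], names[j], diff, p_adj, significance_stars(p_adj))
            )
    return TestResult(
        test="anova",
        statistic=float(f),
        df=float(df_b),
        p_value=min(float(p), 1.0),
        groups=tuple(summarise(d, n) for n, d in zip(names, data)),
        stars=significance_stars(min(float(p), 1.0)),
        pairwise=tuple(pairwise),
    )


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 df.
    """
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided single-outlier Grubbs removal.

    At each pass the most extreme studentised deviate G = max|x - mean|/sd
    is compared with the two-sided critical value at ``alpha``; a rejected
    value is removed and the test repeats until no rejection or until n
    would drop below 3.  Returns (retained values, removed original
    indices, in removal order).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    idx = np.arange(v.size)
    removed: list[int] = []
    while v.size >= 3:
        sd = v.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(v - v.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= grubbs_critical(v.size, alpha):
            break
        removed.append(int(idx[i]))
        keep = np.ones(v.size, dtype=bool)
        keep[i] = False
        v, idx = v[keep], idx[keep]
    return v, removed
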