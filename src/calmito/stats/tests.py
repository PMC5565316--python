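"""Statistical tests for the paired patient/control design.

Paired Wilcoxon signed-rank with an exact two-sided p for small samples
(the study has 15 pairs), uncorrected Pearson chi-squared on 2x2 tables,
Spearman rank correlation, Shapiro-Wilk normality gating and Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: largest n for which the signed-rank null distribution is enumerated
#: exactly (2^15 = 32768 sign assignments; beyond that the normal
#: approximation with tie correction is standard)
EXACT_WILCOXON_MAX_N = 15


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: int
    corrected_p: float | None = None
    normality_p: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ given doubled ranks, by convolution.

    Under the null each |difference| carries its (average) rank with sign +
    or - independently with probability 1/2. Ranks are doubled so average
    ranks (multiples of 0.5) become integers; counts[w] is the number of the
    2^n sign assignments with doubled positive-rank sum w.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def paired_wilcoxon(x, y) -> StatResult:
    """Wilcoxon signed-rank test on within-pair differences x - y.

    Zero differences are dropped (Wilcoxon's convention) and n reported
    after dropping. For n <= 15 the two-sided p is exact:
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) over the full enumeration of
    sign assignments, valid under ties because the distribution conditions
    on the observed |differences|. Larger n uses the normal approximation
    with tie correction (scipy).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero; the paired test is undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        test = "wilcoxon_signed_rank_exact"
    else:
        res = sps.wilcoxon(d, correction=False, method="approx")
        p = float(res.pvalue)
        test = "wilcoxon_signed_rank_approx"
    return StatResult(test=test, statistic=w_plus, p_value=p, n=n)


def mann_whitney(x, y) -> StatResult:
    """Unpaired alternative (sensitivity check), via scipy."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x) + len(y),
    )


def paired_ttest(x, y) -> StatResult:
    """Paired t-test, used when the normality gate allows a parametric test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    res = sps.ttest_rel(x, y)
    return StatResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
    )


def chi2_2x2(table) -> StatResult:
    """Pearson chi-squared on a 2x2 table, WITHOUT continuity correction.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or t.sum() < 1:
        raise ValueError("counts must be >= 0 with total >= 1")
    (a, b), (c, d) = t
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("chi-squared undefined with a zero margin")
    n = t.sum()
    stat = n * (a * d - b * c) ** 2 / np.prod(margins)
    return StatResult(
        test="chi2_2x2",
        statistic=float(stat),
        p_value=float(sps.chi2.sf(stat, df=1)),
        n=int(n),
    )


def spearman_corr(x, y) -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the ranks; the two-sided p uses the
    t approximation t = rho sqrt((n-2)/(1-rho^2)) on n-2 df (p = 0 at
    rho = +/-1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return StatResult(test="spearman", statistic=rho, p_value=p, n=n)


def shapiro_gate(values, alpha: float = 0.05) -> tuple[float, str]:
    """Shapiro-Wilk normality check -> (p, recommended test family).

    Returns 'nonparametric' when normality is rejected at alpha (or the
    sample is degenerate: identical values), else 'parametric'. Defined for
    3 <= n <= 50, the regime of this cohort's per-group samples.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if not (3 <= n <= 50):
        raise ValueError(f"Shapiro-Wilk gate defined for 3 <= n <= 50; got {n}")
    if np.ptp(values) == 0:
        return 0.0, "nonparametric"
    p = float(sps.shapiro(values).pvalue)
    return p, ("nonparametric" if p < alpha else "parametric")


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni correction: each p -> min(1, m * p).

    m defaults to the number of p-values (the family size); it may be larger
    when the family includes tests reported elsewhere, never smaller.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("family size m cannot be below the number of tests")
    out = []
    for p in p_values:
        if np.isnan(p):
            out.append(float("nan"))
            continue
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out
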