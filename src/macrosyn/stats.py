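"""Statistical primitives shared by all analysis stages.

Only the tests actually used downstream live here: exact binomial tail
tests, Benjamini-Hochberg adjustment, Wilcoxon rank-sum (exact for small
samples, normal approximation with tie and continuity correction
otherwise), Pearson correlation, the 2x2 chi-square test of proportions
(no continuity correction), and empirical p-values from permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import TestResult

__all__ = [
    "AdjustedPValues",
    "binomial_test",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "pearson_r",
    "proportion_chisq",
    "empirical_p",
    "percent_change",
]

#: maximum pooled sample size for which the rank-sum test is exact
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "BH"


def _check_sided(sided: str) -> None:
    if sided not in ("one-greater", "two"):
        raise ValueError(f"sided must be 'one-greater' or 'two', got {sided!r}")


def binomial_test(
    successes: int, trials: int, prob: float, sided: str = "one-greater"
) -> TestResult:
    """Exact binomial tail test.

    ``one-greater`` returns P(X >= successes) under Binomial(trials, prob).
    """
    _check_sided(sided)
    if not (0.0 <= prob <= 1.0):
        raise ValueError(f"prob {prob} outside [0, 1]")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if successes < 0 or successes > trials:
        raise ValueError("successes must lie in [0, trials]")
    alternative = "greater" if sided == "one-greater" else "two-sided"
    res = scipy.stats.binomtest(successes, trials, prob, alternative=alternative)
    return TestResult(
        statistic=float(successes),
        p_value=float(min(1.0, res.pvalue)),
        method="binomial",
        n1=trials,
        n2=0,
        sided=sided,
    )


def bh_adjust(pvalues) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    raw = tuple(float(p) for p in pvalues)
    if not raw:
        raise ValueError("cannot adjust an empty p-value list")
    if any(p < 0.0 or p > 1.0 for p in raw):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    return AdjustedPValues(raw=raw, adjusted=tuple(float(a) for a in adj))


def _ranksum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # midranks for ties
    n1 = len(x)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0  # Mann-Whitney U of x (R's W)
    return u, ranks


def wilcoxon_rank_sum(x, y, sided: str = "two") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    Exact p by enumeration of all group assignments when n1 + n2 <= 20;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction. The reported statistic is the Mann-Whitney U of
    the first sample, identical to R's ``wilcox.test`` W.
    """
    _check_sided(sided)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    u, ranks = _ranksum_u(x, y)
    mean_u = n1 * n2 / 2.0

    if n <= EXACT_RANKSUM_MAX_N:
        # work on twice-the-rank integers: midranks live on a 0.5 grid
        r2 = np.rint(2 * ranks).astype(np.int64)
        u2 = int(round(2 * u))
        base = n1 * (n1 + 1)  # 2 * n1(n1+1)/2
        mean2 = int(round(2 * mean_u))
        sums = np.fromiter(
            (sum(c) for c in combinations(r2.tolist(), n1)),
            dtype=np.int64,
        )
        u_all = sums - base
        total = u_all.size
        if sided == "one-greater":
            p = float(np.count_nonzero(u_all >= u2)) / total
        else:
            dev = np.abs(u_all - mean2)
            p = float(np.count_nonzero(dev >= abs(u2 - mean2))) / total
        method = "wilcoxon-exact"
    else:
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:
            # all values identical: no evidence of shift
            p = 1.0
            method = "wilcoxon-normal"
        else:
            sd = np.sqrt(var_u)
            if sided == "one-greater":
                z = (u - mean_u - 0.5) / sd
                p = float(scipy.stats.norm.sf(z))
            else:
                z = (abs(u - mean_u) - 0.5) / sd
                p = float(min(1.0, 2.0 * scipy.stats.norm.sf(max(z, 0.0))))
            method = "wilcoxon-normal"
    return TestResult(
        statistic=u, p_value=p, method=method, n1=n1, n2=n2, sided=sided
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="pearson",
        n1=int(x.size),
        n2=int(y.size),
        sided="two",
    )


def proportion_chisq(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """2x2 chi-square test of two proportions, df = 1, no continuity
    correction (the genome-scale counts this serves make Yates irrelevant)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("trial counts must be >= 1")
        if not (0 <= k <= n):
            raise ValueError("successes must lie in [0, trials]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero expected cell in 2x2 table")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        method="chisq-2x2",
        n1=n1,
        n2=n2,
        sided="two",
    )


def empirical_p(observed: float, null_values) -> tuple[float, float]:
    """Empirical p-values for an observed statistic against a permutation null.

    Returns ``(p_empirical, p_conservative)`` where ``p_empirical`` is the plain
    #(null >= observed)/N estimator (may be exactly 0) and
    ``p_conservative`` is the add-one estimator (#(null >= observed)+1)/(N+1).
    """
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    n_ge = int(np.count_nonzero(null >= observed))
    return n_ge / null.size, (n_ge + 1) / (null.size + 1)


def percent_change(old: float, new: float, ndigits: int = 0) -> float:
    """Percent change from ``old`` to ``new``, rounded to ``ndigits``."""
    if old <= 0:
        raise ValueError("old value must be positive")
    return round(100.0 * (new - old) / old, ndigits)
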