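"""Exact and asymptotic statistics shared by the interactome analyses.

All contingency machinery works on 2x2 tables.  The one-sided exact test is
the hypergeometric upper tail (enrichment of the ``a`` cell with margins
fixed); the chi-square test is the classic df=1 statistic without continuity
correction, which is the convention that reproduces published adverse-event
report-rate comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Table2x2",
    "hypergeom_upper_tail",
    "fisher_one_sided",
    "chi_square_2x2",
    "pearson_pairwise",
    "ks_two_sample",
    "P_FLOOR",
]

#: Reported p values are floored here; tails below this are numerically moot.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class Table2x2:
    """Four non-negative integer cells; row/column semantics are the caller's.

    Convention used throughout this package: ``a`` is the cell whose
    over-representation is tested (e.g. case & interactive), with ``b`` its
    row neighbour and ``c``/``d`` the second row.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        for x in cells:
            if int(x) != x or x < 0:
                raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("all four cells are zero")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of successes in the population,
    n the sample size, k the observed successes.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if k < 0:
        raise ValueError(f"require k >= 0, got k={k}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    # scipy's sf accumulates the tail from log-space pmf values
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def fisher_one_sided(t: Table2x2) -> float:
    """One-sided Fisher exact p for over-representation of the ``a`` cell.

    Equals the hypergeometric upper tail P(X >= a) with population n,
    K = a + c population successes and n_draw = a + b draws (margins fixed).
    """
    # a <= min(a+c, a+b), so the tail is never empty and p > 0 always
    p = hypergeom_upper_tail(t.a, t.n, t.a + t.c, t.a + t.b)
    return max(p, P_FLOOR)


def chi_square_2x2(t: Table2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    statistic = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]; p is the upper tail
    of chi-square(1).  Any zero margin leaves the statistic undefined.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError(f"zero margin in table {(t.a, t.b, t.c, t.d)}")
    stat = t.n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), max(p, P_FLOOR) if p > 0 else P_FLOOR


def pearson_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over pairwise-complete positions.

    Positions where either vector is NaN are dropped; at least 3 complete
    pairs with non-zero variance on both sides are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} complete pairs; need >= 3")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in a pairwise-complete vector")
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum ECDF distance; the p value uses the standard asymptotic
    two-sample formula.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
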