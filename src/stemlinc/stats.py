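"""Exact and rank statistics with multiple-testing adjustment.

The enrichment machinery downstream needs four ingredients: the
hypergeometric over-representation tail, Fisher's exact test on 2×2 tables,
the Wilcoxon rank-sum test, and the Benjamini–Hochberg / Benjamini–
Yekutieli step-up adjustments. Conventions:

* The reported odds ratio is the sample (cross-product) ratio ad/bc, with
  +inf when bc = 0 and ad > 0, and 1 when both products vanish.
* One-sided "greater" Fisher p is P(A >= a) under the margin-conditioned
  hypergeometric; the two-sided p sums all tables with probability not
  exceeding the observed one (the standard small-p rule).
* The rank-sum test enumerates all labelings exactly for small samples
  (combined n <= 12 by default, midranks under ties) and otherwise uses
  the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError

SIDEDNESS = ("greater", "less", "two_sided")


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows in-set/out-set, cols with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise DataError("empty contingency table")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str


@dataclass
class EnrichmentResult:
    """A 2×2 enrichment outcome for one term or feature."""

    name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None
    significant: bool | None = None
    reason: str | None = None


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n).

    N = universe size, K = annotated in universe, n = drawn, k = observed
    annotated among the drawn.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise DataError(
            f"hypergeometric bounds violated: N={N}, K={K}, n={n}, k={k}"
        )
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample (cross-product) odds ratio ad/bc with the +inf/1 conventions."""
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.inf if ad > 0 else 1.0
    return ad / bc


def fisher_exact(t: ContingencyTable2x2, sidedness: str = "greater") -> TestResult:
    """Fisher's exact test on a 2×2 table.

    The p-value comes from the hypergeometric distribution of cell ``a``
    conditional on the table margins.
    """
    if sidedness not in SIDEDNESS:
        raise DataError(f"unknown sidedness {sidedness!r}")
    N = t.a + t.b + t.c + t.d
    r1, c1 = t.a + t.b, t.a + t.c
    a_min, a_max = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    pmf = sps.hypergeom.pmf(support, N, c1, r1)
    p_obs = pmf[t.a - a_min]
    if sidedness == "greater":
        p = pmf[support >= t.a].sum()
    elif sidedness == "less":
        p = pmf[support <= t.a].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return TestResult(odds_ratio(t), float(min(1.0, p)), sidedness)


def _exact_ranksum_p(ranks: np.ndarray, m: int, w_obs: float) -> tuple[float, float]:
    """Exact (P(W <= w), P(W >= w)) by enumerating all C(m+n, m) labelings."""
    total = 0
    n_le = n_ge = 0
    eps = 1e-9
    for idx in combinations(range(len(ranks)), m):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return n_le / total, n_ge / total


def ranksum_test(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two_sided",
    exact_max: int = 12,
) -> TestResult:
    """Wilcoxon rank-sum test; statistic is the rank sum of ``x``.

    Exact permutation p-value when len(x)+len(y) <= ``exact_max``
    (midranks under ties); otherwise normal approximation with tie
    correction and a 0.5 continuity correction. "greater" means x tends
    to exceed y.
    """
    if sidedness not in SIDEDNESS:
        raise DataError(f"unknown sidedness {sidedness!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise DataError("rank-sum test needs non-empty samples")
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:m].sum())
    if m + n <= exact_max:
        p_le, p_ge = _exact_ranksum_p(ranks, m, w)
    else:
        mean = m * (m + n + 1) / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((m + n) * (m + n - 1))
        var = m * n / 12.0 * ((m + n + 1) - tie_term)
        if var <= 0:  # all values tied
            p_le = p_ge = 1.0
        else:
            sd = math.sqrt(var)
            p_ge = float(sps.norm.sf((w - mean - 0.5) / sd))
            p_le = float(sps.norm.cdf((w - mean + 0.5) / sd))
    if sidedness == "greater":
        p = p_ge
    elif sidedness == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(w, float(p), sidedness)


def _check_pvalues(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, float)
    if arr.size and ((arr < 0).any() or (arr > 1).any() or np.isnan(arr).any()):
        raise DataError("p-values must lie in [0, 1]")
    return arr


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = _check_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def adjust_by(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli adjustment: BH scaled by c(m) = Σ 1/i, clipped at 1."""
    arr = _check_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_by")[1]
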