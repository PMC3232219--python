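"""Small-sample exact statistics shared across modules.

Wilcoxon signed-rank is exact for n <= 25 (no tied or zero differences) and
falls back to the normal approximation with continuity and tie correction
otherwise.  Spearman p-values are exact permutation p for n <= 9 and use the
tie-corrected t approximation above that.  These choices matter for p-values
near classification thresholds, so they are centralized here.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats

WILCOXON_EXACT_MAX_N = 25
SPEARMAN_EXACT_MAX_N = 9


def wilcoxon_signed_rank(values, alternative: str = "two-sided") -> tuple[float, float]:
    """Signed-rank test of median 0. Returns (median, p).

    Zero differences are dropped (the classical treatment); if everything is
    zero the test is vacuous and p = 1.
    """
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr)) if len(arr) else np.nan
    nz = arr[arr != 0.0]
    if len(nz) == 0:
        return med, 1.0
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    if len(nz) <= WILCOXON_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        nz, alternative=alternative, method=method, correction=(method == "approx")
    )
    return med, float(res.pvalue)


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)


def spearman(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rho with an exact permutation p for n <= 9.

    With ties, average ranks are used in both the statistic and the
    permutation null.  Returns (rho, p); rho is NaN for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > SPEARMAN_EXACT_MAX_N:
        res = stats.spearmanr(x, y, alternative=alternative)
        return rho, float(res.pvalue)
    # exact permutation distribution of rho over all orderings of y's ranks
    perms = _rank_permutations(n)
    ry_sorted = np.sort(ry)
    perm_ranks = ry_sorted[perms.astype(int) - 1]
    rx_c = rx - rx.mean()
    pr_c = perm_ranks - perm_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c @ rx_c) * np.sum(pr_c**2, axis=1))
    rhos = (pr_c @ rx_c) / denom
    eps = 1e-12
    if alternative == "two-sided":
        p = np.mean(np.abs(rhos) >= abs(rho) - eps)
    elif alternative == "greater":
        p = np.mean(rhos >= rho - eps)
    elif alternative == "less":
        p = np.mean(rhos <= rho + eps)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return rho, float(p)


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    return float(stats.binom.sf(k - 1, n, p0))
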