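"""Shared statistical primitives used across the pipeline.

Everything here is a thin, explicitly-contracted wrapper over scipy /
statsmodels, plus the handful of primitives (vectorised Spearman with an
exact small-n null, partial Spearman, enrichment ratios) that the stages
share.  Keeping them in one place guarantees that e.g. every BH correction
in the pipeline is the same BH correction.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "percent",
    "bh_fdr",
    "spearman",
    "spearman_matrix",
    "spearman_pvalues",
    "partial_spearman",
    "fisher_2x2",
    "rate_ratio",
    "enrichment_2x2",
]


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to `decimals`.

    The single utility through which every reported fraction in the
    pipeline's summary tables is formatted, so printed percentages are
    reproducible from their printed numerator/denominator.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@lru_cache(maxsize=None)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted |rho| null distribution over all n! rank permutations."""
    ident = np.arange(n)
    denom = n * (n * n - 1)
    rhos = np.array(
        [1.0 - 6.0 * np.sum((np.array(p) - ident) ** 2) / denom
         for p in itertools.permutations(range(n))]
    )
    return np.sort(np.abs(rhos))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation with n-2 df."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    p is exact (full permutation null) for n <= 9 without ties, otherwise
    the t approximation with n-2 degrees of freedom.  Returns (nan, nan)
    if either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    rho = sps.spearmanr(x, y).statistic
    n = len(x)
    if n <= 9 and not (_has_ties(x) or _has_ties(y)):
        null = _exact_spearman_null(n)
        # right-tail count on the sorted |rho| null, with fp tolerance
        k = np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float(rho), float((len(null) - k) / len(null))
    return float(rho), float(np.atleast_1d(_t_approx_p(np.array(rho), n))[0])


def _rank_standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise ranks, centred and scaled to unit norm; flags constant rows."""
    R = np.apply_along_axis(sps.rankdata, 1, M.astype(float))
    R -= R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    return R / norms[:, None], constant


def spearman_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rho between rows of X and rows of Y.

    X is (p, n), Y is (q, n); result is (p, q).  Constant rows give NaN.
    """
    Rx, cx = _rank_standardize(np.asarray(X))
    Ry, cy = _rank_standardize(np.asarray(Y))
    rho = Rx @ Ry.T
    rho[cx, :] = np.nan
    rho[:, cy] = np.nan
    return np.clip(rho, -1.0, 1.0)


def spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation p-values for a matrix of Spearman rhos."""
    return _t_approx_p(rho, n)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given z.

    Rank-transforms all three vectors, removes the linear dependence on the
    ranks of z by least squares, and correlates the residuals; the p-value
    uses the t approximation with n-3 degrees of freedom (one df spent on
    the conditioning variable).
    """
    rx = sps.rankdata(np.asarray(x, dtype=float))
    ry = sps.rankdata(np.asarray(y, dtype=float))
    rz = sps.rankdata(np.asarray(z, dtype=float))
    n = len(rx)
    Z = np.column_stack([np.ones(n), rz])
    ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    # residuals that vanish up to floating point are degenerate (x or y is
    # an exact function of z); without the tolerance the leftover 1e-13
    # noise would correlate perfectly
    tol = 1e-8 * n
    if ex.std() <= tol or ey.std() <= tol:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(ex, ey)[0, 1])
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 3) / (1.0 - rho**2))
    return rho, float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 3)))


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds_ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def rate_ratio(table) -> float:
    """Rate ratio (a/(a+b)) / (c/(c+d)) for a 2x2 table [[a,b],[c,d]].

    NaN when a margin is empty, inf when the reference rate is zero but the
    focal rate is not.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        return float("nan")
    r1, r2 = a / n1, c / n2
    if r2 == 0:
        return float("inf") if r1 > 0 else float("nan")
    return float(r1 / r2)


def enrichment_2x2(table) -> dict:
    """Enrichment ratio (rate ratio), odds ratio and Fisher p for a 2x2."""
    odds, p = fisher_2x2(table)
    return {
        "enrichment_ratio": rate_ratio(table),
        "odds_ratio": odds,
        "p": p,
        "table": [list(map(int, row)) for row in np.asarray(table)],
    }
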