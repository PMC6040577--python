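"""Exact and closed-form statistics used throughout the pipeline.

All tests here are small-sample exact procedures: the sign test is the
exact binomial tail at success probability 1/2 (no normal approximation),
Fisher's combined probability is the chi-square transform of log P values,
and Pearson P values come from the exact t transformation with n - 2
degrees of freedom.

One-tailed sign-test P values are always the exact upper tail
P(X >= s | n, 1/2).  Two-tailed P values are the doubled smaller tail,
capped at 1.  Degenerate correlation inputs (fewer than 3 points, or a
constant vector) yield ``None`` — a flagged missing value — rather than
NaN propagation or an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SignTestResult",
    "CombinedP",
    "PearsonResult",
    "sign_test",
    "fisher_combine",
    "fdr_critical",
    "pearson",
    "spearman",
]


@dataclass(frozen=True)
class SignTestResult:
    """Exact binomial sign test of ``s`` successes in ``n`` trials at p = 1/2."""

    n: int
    s: int
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class CombinedP:
    """Fisher combination: chi_square = -2 sum(ln P_i), df = 2 x #tests."""

    chi_square: float
    df: int
    p: float


@dataclass(frozen=True)
class PearsonResult:
    """Pearson correlation with exact-t one- and two-tailed P values.

    ``p_one_tailed`` is for the direction stated when the correlation was
    computed (negative unless specified otherwise).
    """

    r: float
    p_one_tailed: float
    p_two_tailed: float
    n: int
    direction: str = "negative"


def sign_test(s: int, n: int) -> SignTestResult:
    """Exact sign test: probability of >= ``s`` successes in ``n`` fair trials.

    Parameters
    ----------
    s : number of outcomes in the predicted direction.
    n : number of trials, at least 1.

    Returns
    -------
    SignTestResult with the exact one-tailed upper tail
    ``P(X >= s | n, 1/2)`` and the doubled-smaller-tail two-tailed P.
    """
    if n < 1:
        raise ValueError(f"sign test needs n >= 1 trials, got {n}")
    if not 0 <= s <= n:
        raise ValueError(f"successes s={s} outside [0, n={n}]")
    tail_high = float(sps.binom.sf(s - 1, n, 0.5))  # P(X >= s)
    tail_low = float(sps.binom.cdf(s, n, 0.5))      # P(X <= s)
    p_two = min(1.0, 2.0 * min(tail_high, tail_low))
    return SignTestResult(n=n, s=s, p_one_tailed=tail_high, p_two_tailed=p_two)


def fisher_combine(p_values: Sequence[float]) -> CombinedP:
    """Combine independent P values by Fisher's method.

    The statistic -2 * sum(ln P_i) follows a chi-square distribution with
    2k degrees of freedom under the joint null (k = number of tests).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one P value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("all P values must lie in (0, 1]")
    chi_square = float(-2.0 * np.log(p).sum())
    df = 2 * int(p.size)
    return CombinedP(chi_square=chi_square, df=df, p=float(sps.chi2.sf(chi_square, df)))


def fdr_critical(alpha: float, k: int) -> float:
    """Critical significance level controlling the mean false discovery rate
    for ``k`` dependent tests: alpha * (k + 1) / (2 k).

    For k = 1 this is alpha itself; it decreases toward alpha / 2 as the
    number of tests grows.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise ValueError(f"number of tests k must be >= 1, got {k}")
    return alpha * (k + 1) / (2 * k)


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "negative",
) -> Optional[PearsonResult]:
    """Pearson correlation with exact-t P values.

    Parameters
    ----------
    x, y : equal-length numeric vectors.
    direction : "negative" or "positive"; the one-tailed P is the tail
        probability of a correlation at least as extreme in that direction.

    Returns
    -------
    PearsonResult, or ``None`` (flagged missing) when fewer than 3 pairs
    remain or either vector is constant.
    """
    if direction not in ("negative", "positive"):
        raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        return None
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return None
    alt = "less" if direction == "negative" else "greater"
    res_two = sps.pearsonr(xa, ya)
    res_one = sps.pearsonr(xa, ya, alternative=alt)
    r = float(res_two.statistic)
    return PearsonResult(
        r=r,
        p_one_tailed=float(res_one.pvalue),
        p_two_tailed=float(res_two.pvalue),
        n=n,
        direction=direction,
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "negative",
) -> Optional[PearsonResult]:
    """Spearman rank correlation as rank-transformed Pearson."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        return None
    return pearson(sps.rankdata(xa), sps.rankdata(ya), direction=direction)


def _nan_or(value: Optional[PearsonResult], attr: str) -> float:
    """Pull an attribute off an optional correlation result, NaN if missing."""
    return math.nan if value is None else getattr(value, attr)
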