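"""Rank and correlation statistics used by the cohort associations.

Self-contained implementations so that small-sample behaviour is fully
specified: the Mann-Whitney U test enumerates every labelling of the observed
pooled data when the samples are small (a conditional-on-data exact test,
midranks for ties), and falls back to the tie-corrected normal approximation
with continuity correction otherwise.  Pearson's r gets its two-sided p-value
from the usual t transform with n-2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from scipy.special import stdtr

__all__ = ["CorrelationResult", "RankTestResult", "mann_whitney_u", "pearson_r", "midranks"]

EXACT_LIMIT = 16  # full enumeration up to C(16, 8) = 12,870 labellings


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "normal-approximation"
    degenerate: bool = False


def midranks(values: Sequence[float]) -> list[float]:
    """Midrank of each value in its list (average rank over ties, 1-based)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto", exact_limit: int = EXACT_LIMIT
) -> RankTestResult:
    """Two-sided Mann-Whitney U test of ``a`` vs ``b``.

    ``mode`` is "auto" (exact when n1+n2 <= ``exact_limit``), "exact" or
    "approx".  The exact two-sided p doubles the smaller tail of the
    enumeration distribution (capped at 1).  When every pooled value is tied
    the test is degenerate and p = 1.
    """
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode: {mode}")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    u = _u_from_ranks(sum(ranks[:n1]), n1)

    if len(set(pooled)) == 1:
        return RankTestResult(u, 1.0, n1, n2, "exact", degenerate=True)

    exact = mode == "exact" or (mode == "auto" and n <= exact_limit)
    if exact:
        lo = hi = total = 0
        for idx in combinations(range(n), n1):
            ui = _u_from_ranks(sum(ranks[i] for i in idx), n1)
            total += 1
            if ui <= u + 1e-9:
                lo += 1
            if ui >= u - 1e-9:
                hi += 1
        p = min(1.0, 2 * min(lo, hi) / total)
        return RankTestResult(u, p, n1, n2, "exact")

    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2
    tie_sum = 0.0
    seen: dict[float, int] = {}
    for v in pooled:
        seen[v] = seen.get(v, 0) + 1
    for t in seen.values():
        tie_sum += t**3 - t
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_sum / (n * (n - 1)))
    if sigma2 <= 0:
        return RankTestResult(u, 1.0, n1, n2, "normal-approximation", degenerate=True)
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2))
    return RankTestResult(u, min(1.0, p), n1, n2, "normal-approximation")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    Requires n >= 3 and non-degenerate variance in both variables.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0 or syy == 0:
        raise ValueError("undefined correlation: zero variance")
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r * r))
        p = 2 * float(stdtr(df, -abs(t)))
    return CorrelationResult(r, p, n)
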