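"""Independent brute-force oracles for the statistics the package computes.

Everything here is coded directly from the defining formulas with plain
Python loops — deliberately independent of the vectorized implementation
paths in :mod:`tlv` so the two can cross-check each other.
"""

from __future__ import annotations

import math
from itertools import combinations


def mean(xs) -> float:
    return sum(xs) / len(xs)


def sample_sd(xs) -> float:
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def cv_percent(xs) -> float:
    return 100.0 * sample_sd(xs) / mean(xs)


def median(xs) -> float:
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def percentile_inclusive(xs, p: float) -> float:
    """Spreadsheet inclusive convention: h = p*(n-1)+1 between order stats."""
    s = sorted(xs)
    h = p * (len(s) - 1) + 1
    lo = int(math.floor(h))
    frac = h - lo
    if lo >= len(s):
        return s[-1]
    return s[lo - 1] + frac * (s[lo] - s[lo - 1])


def skewness(xs) -> float:
    """Bias-corrected (spreadsheet SKEW): n/((n-1)(n-2)) * sum(((x-m)/s)^3)."""
    n = len(xs)
    m, s = mean(xs), sample_sd(xs)
    return n / ((n - 1) * (n - 2)) * sum(((x - m) / s) ** 3 for x in xs)


def excess_kurtosis(xs) -> float:
    """Bias-corrected (spreadsheet KURT) excess kurtosis."""
    n = len(xs)
    m, s = mean(xs), sample_sd(xs)
    term = sum(((x - m) / s) ** 4 for x in xs)
    return (n * (n + 1) / ((n - 1) * (n - 2) * (n - 3))) * term \
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))


def least_squares_slope(ys, xs=None) -> float:
    """Slope of y on x (default x = rank 1..n), by the textbook formula."""
    n = len(ys)
    if xs is None:
        xs = list(range(1, n + 1))
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = sum((x - mx) ** 2 for x in xs)
    return num / den


def pearson_r(xs, ys) -> float:
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)


def r_squared_vs_rank(sorted_ys) -> float:
    n = len(sorted_ys)
    return pearson_r(list(range(1, n + 1)), list(sorted_ys)) ** 2


def segment_slopes(sorted_ys, m_end: int):
    """Q1 / Q2+Q3 / Q4 slopes with end segments of m_end ranks."""
    n = len(sorted_ys)
    ranks = list(range(1, n + 1))
    s1 = least_squares_slope(sorted_ys[:m_end], ranks[:m_end])
    s23 = least_squares_slope(sorted_ys[m_end:n - m_end], ranks[m_end:n - m_end])
    s4 = least_squares_slope(sorted_ys[n - m_end:], ranks[n - m_end:])
    return s1, s23, s4


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all n-subsets of N items.

    The set is taken as the first K of N labelled items; every C(N, n)
    draw is enumerated and counted. Feasible for N <= 12.
    """
    return hypergeom_tail_probs(N, K, n)[k]


def hypergeom_tail_probs(N: int, K: int, n: int) -> list:
    """Upper-tail probabilities P(X >= k) for k = 0..n, by enumeration."""
    counts = [0] * (n + 1)
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        counts[sum(1 for item in draw if item < K)] += 1
    tails = [0.0] * (n + 1)
    acc = 0
    for k in range(n, -1, -1):
        acc += counts[k]
        tails[k] = acc / total
    return tails


def bh_step_up(ps):
    """Benjamini–Hochberg adjusted values: q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, ps[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
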