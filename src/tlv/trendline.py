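"""Rank-order trendlines and the per-gene tailedness statistics suite.

A *trendline* is one gene's counts across the sample group sorted
ascending. Genes whose counts are draws from a common (roughly normal)
within-group distribution produce near-linear trendlines once
rank-ordered; genes elevated in a subset of individuals produce
trendlines with a steep final quartile ("tailedness"). The statistics
computed here quantify that departure:

=================  =====================================================
statistic          meaning
=================  =====================================================
cv                 100 * sd / mean (percent)
max_min_ratio      max / min count
range_over_median  (max - min) / median
range_over_q3      (max - min) / 75th-percentile value
skewness           bias-corrected sample skewness (spreadsheet SKEW)
excess_kurtosis    bias-corrected excess kurtosis (spreadsheet KURT)
slope, r_squared   least-squares fit of count against rank 1..n
slope_q1/q23/q4    segment slopes over the first, middle and last
                   quartiles of ranks
ratio_q1/ratio_q4  slope_q1 / slope_q23 and slope_q4 / slope_q23
=================  =====================================================

Percentiles use the inclusive linear-interpolation convention
(plotting position h = p*(n-1) + 1), the default of both spreadsheet
QUARTILE.INC and :func:`numpy.quantile`.

Degenerate cases are kept in the table and flagged rather than dropped:
constant genes report sd = cv = slope = 0 and r_squared = 0 with a
``constant`` flag; a zero median (or minimum) with nonzero range makes
the corresponding ratio infinite, with an ``inf_*`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scaling import ScaledMatrix

__all__ = [
    "Trendline",
    "build_trendline",
    "percentile_inclusive",
    "compute_trendline_record",
    "quartile_segment_slopes",
    "quartile_segment_sizes",
    "stats_table",
    "STAT_COLUMNS",
    "SCALE_FREE_STATS",
]

STAT_COLUMNS = [
    "n", "mean", "median", "sd", "cv", "min", "max", "range",
    "max_min_ratio", "q1_value", "q3_value", "range_over_median",
    "range_over_q3", "skewness", "excess_kurtosis", "slope", "r_squared",
    "slope_q1", "slope_q23", "slope_q4", "ratio_q1", "ratio_q4", "flags",
]

#: statistics invariant under positive per-gene rescaling (raw vs MVA)
SCALE_FREE_STATS = [
    "cv", "max_min_ratio", "range_over_median", "range_over_q3",
    "skewness", "excess_kurtosis", "r_squared", "ratio_q1", "ratio_q4",
]


@dataclass
class Trendline:
    """One gene's counts sorted ascending, with sample provenance.

    ``sample_at_rank[i]`` is the sample holding rank i+1 (lowest count is
    rank 1). Ties are broken by sample-ID lexical order so the permutation
    is deterministic.
    """

    gene_id: str
    sorted_values: np.ndarray
    sample_at_rank: list[str]


def build_trendline(values: pd.Series, gene_id: str | None = None) -> Trendline:
    """Sort one gene's counts ascending, recording which sample sits where."""
    if len(values) < 2:
        raise ValueError("a trendline needs at least 2 samples")
    order = sorted(range(len(values)), key=lambda i: (values.iloc[i], str(values.index[i])))
    return Trendline(
        gene_id=gene_id if gene_id is not None else str(values.name),
        sorted_values=values.to_numpy(dtype=float)[order],
        sample_at_rank=[str(values.index[i]) for i in order],
    )


def percentile_inclusive(sorted_values: np.ndarray, p: float) -> float:
    """Inclusive-convention percentile: h = p*(n-1)+1 between order stats."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"percentile fraction {p} outside [0, 1]")
    return float(np.quantile(np.asarray(sorted_values, dtype=float), p, method="linear"))


def quartile_segment_sizes(n: int) -> tuple[int, int, int]:
    """Rank counts of the Q1 / Q2+Q3 / Q4 segments: round(n/4) at each end."""
    m = int(np.floor(n / 4 + 0.5))
    return m, n - 2 * m, m


def _segment_slope(y: np.ndarray, ranks: np.ndarray) -> float:
    """Least-squares slope of y against rank (>= 2 points)."""
    r = ranks - ranks.mean()
    return float((r * (y - y.mean())).sum() / (r * r).sum())


def quartile_segment_slopes(
    t: Trendline | np.ndarray, boundaries: tuple[int, int, int] | None = None
) -> dict[str, float]:
    """Segment least-squares slopes over Q1, Q2+Q3 and Q4 ranks.

    ``ratio_q1 = slope_q1/slope_q23`` and ``ratio_q4 = slope_q4/slope_q23``
    diagnose where a trendline bends: a linear trendline has both ratios
    at 1, a tailed gene has ``ratio_q4`` well above 1. A flat middle
    segment (slope 0) makes the ratios infinite. Intended for n >= 16 so
    every segment holds enough points for a stable fit.
    """
    y = t.sorted_values if isinstance(t, Trendline) else np.asarray(t, dtype=float)
    n = len(y)
    m1, mid, m4 = boundaries if boundaries is not None else quartile_segment_sizes(n)
    if min(m1, mid, m4) < 2:
        raise ValueError(
            f"quartile segments of sizes {m1}/{mid}/{m4} need >= 2 points each"
        )
    ranks = np.arange(1, n + 1, dtype=float)
    s1 = _segment_slope(y[:m1], ranks[:m1])
    s23 = _segment_slope(y[m1:m1 + mid], ranks[m1:m1 + mid])
    s4 = _segment_slope(y[n - m4:], ranks[n - m4:])

    def _ratio(num: float, den: float) -> float:
        if den == 0:
            return np.nan if num == 0 else np.inf * np.sign(num)
        return num / den

    return {
        "slope_q1": s1,
        "slope_q23": s23,
        "slope_q4": s4,
        "ratio_q1": _ratio(s1, s23),
        "ratio_q4": _ratio(s4, s23),
    }


def _stats_block(sorted_rows: np.ndarray) -> pd.DataFrame:
    """Vectorized statistics for an array of per-gene sorted values."""
    g, n = sorted_rows.shape
    y = sorted_rows
    mean = y.mean(axis=1)
    sd = y.std(axis=1, ddof=1)
    median = np.median(y, axis=1)
    vmin = y[:, 0]
    vmax = y[:, -1]
    vrange = vmax - vmin
    q1 = np.quantile(y, 0.25, axis=1, method="linear")
    q3 = np.quantile(y, 0.75, axis=1, method="linear")

    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / mean, 0.0)
        max_min = np.where(vmin != 0, vmax / vmin,
                           np.where(vrange == 0, np.nan, np.inf))
        r_over_med = np.where(median != 0, vrange / median,
                              np.where(vrange == 0, np.nan, np.inf))
        r_over_q3 = np.where(q3 != 0, vrange / q3,
                             np.where(vrange == 0, np.nan, np.inf))

    constant = sd == 0
    # spreadsheet-convention (bias-corrected) shape statistics
    skew = np.full(g, np.nan)
    kurt = np.full(g, np.nan)
    ok = ~constant
    if n >= 3 and ok.any():
        skew[ok] = sps.skew(y[ok], axis=1, bias=False)
    if n >= 4 and ok.any():
        kurt[ok] = sps.kurtosis(y[ok], axis=1, bias=False, fisher=True)

    ranks = np.arange(1, n + 1, dtype=float)
    rc = ranks - ranks.mean()
    yc = y - mean[:, None]
    slope = (yc * rc).sum(axis=1) / (rc * rc).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(
            constant, 0.0,
            ((yc * rc).sum(axis=1)) ** 2
            / ((yc * yc).sum(axis=1) * (rc * rc).sum()),
        )
    slope = np.where(constant, 0.0, slope)

    seg = {k: np.full(g, np.nan) for k in
           ("slope_q1", "slope_q23", "slope_q4", "ratio_q1", "ratio_q4")}
    m1, mid, m4 = quartile_segment_sizes(n)
    if min(m1, mid, m4) >= 2:
        def _block_slope(yb: np.ndarray, rb: np.ndarray) -> np.ndarray:
            rcb = rb - rb.mean()
            ycb = yb - yb.mean(axis=1, keepdims=True)
            return (ycb * rcb).sum(axis=1) / (rcb * rcb).sum()

        s1 = _block_slope(y[:, :m1], ranks[:m1])
        s23 = _block_slope(y[:, m1:m1 + mid], ranks[m1:m1 + mid])
        s4 = _block_slope(y[:, n - m4:], ranks[n - m4:])
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(s23 != 0, s1 / s23,
                          np.where(s1 == 0, np.nan, np.inf * np.sign(s1)))
            r4 = np.where(s23 != 0, s4 / s23,
                          np.where(s4 == 0, np.nan, np.inf * np.sign(s4)))
        seg = {"slope_q1": s1, "slope_q23": s23, "slope_q4": s4,
               "ratio_q1": r1, "ratio_q4": r4}

    flags = np.char.add(
        np.where(constant, "constant;", ""),
        np.char.add(
            np.where(np.isinf(r_over_med), "inf_range_over_median;", ""),
            np.char.add(
                np.where(np.isinf(max_min), "inf_max_min_ratio;", ""),
                np.where(np.isinf(seg["ratio_q4"]) | np.isinf(seg["ratio_q1"]),
                         "inf_slope_ratio;", ""),
            ),
        ),
    )
    if n < 4:
        flags = np.char.add(flags, "kurtosis_undefined;")

    return pd.DataFrame({
        "n": n, "mean": mean, "median": median, "sd": sd, "cv": cv,
        "min": vmin, "max": vmax, "range": vrange, "max_min_ratio": max_min,
        "q1_value": q1, "q3_value": q3, "range_over_median": r_over_med,
        "range_over_q3": r_over_q3, "skewness": skew,
        "excess_kurtosis": kurt, "slope": slope, "r_squared": r2,
        "slope_q1": seg["slope_q1"], "slope_q23": seg["slope_q23"],
        "slope_q4": seg["slope_q4"], "ratio_q1": seg["ratio_q1"],
        "ratio_q4": seg["ratio_q4"],
        "flags": [f.rstrip(";") for f in flags],
    })


def compute_trendline_record(t: Trendline) -> dict:
    """Full statistics bundle for a single gene trendline."""
    block = _stats_block(t.sorted_values[None, :])
    rec = block.iloc[0].to_dict()
    rec["gene_id"] = t.gene_id
    rec["n"] = int(rec["n"])
    return rec


def stats_table(
    m: pd.DataFrame | ScaledMatrix, raw: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One :data:`STAT_COLUMNS` row per gene (rows sorted internally).

    ``m`` is typically the MVA-scaled matrix. If the unadjusted matrix is
    also supplied as ``raw``, a ``raw_mean`` column is appended (used by
    stable-reference-gene selection) and scaling flags are merged in.
    """
    if isinstance(m, ScaledMatrix):
        df, scale_flags = m.values, m.flags
    else:
        df, scale_flags = m, None
    if df.empty:
        raise ValueError("empty matrix")
    sorted_rows = np.sort(df.to_numpy(dtype=float), axis=1)
    table = _stats_block(sorted_rows)
    table.index = df.index
    table.index.name = "gene_id"
    if scale_flags is not None:
        joined = [
            ";".join(x for x in (a, b) if x)
            for a, b in zip(table["flags"], scale_flags.reindex(df.index).fillna(""))
        ]
        table["flags"] = joined
    if raw is not None:
        table["raw_mean"] = raw.reindex(df.index).mean(axis=1)
    return table
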