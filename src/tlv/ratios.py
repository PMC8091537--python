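"""Stable reference genes and per-sample gene-expression ratios.

A gene whose trendline is highly linear (R^2 above ~0.96) at a usable
raw expression level (mean above ~5 counts) behaves as an internal
reference: expressing another gene as a per-sample ratio to it cancels
depth and global technical effects, so the spread of the 35 ratios
(``fold_range`` = max/min) isolates sample-specific biology. Stable
gene pairs show ~2-fold ranges; genes driven by coordinated responses
in a few individuals show 50-fold and larger ranges concentrated in
exactly those individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RatioProfile", "stable_gene_candidates", "gene_ratio", "format_fold_range"]


@dataclass
class RatioProfile:
    """Per-sample expression ratios of one gene to a reference gene."""

    numerator: str
    denominator: str
    ratios: pd.Series
    min_ratio: float
    max_ratio: float
    fold_range: float
    fold_range_display: float


def format_fold_range(x: float) -> float:
    """Presentation rounding: nearest integer when >= 10, one decimal below.

    Half-values round up (115.5 -> 116).
    """
    if x >= 10:
        return float(math.floor(x + 0.5))
    return float(np.round(x, 1))


def stable_gene_candidates(
    stats_tables: list[pd.DataFrame] | pd.DataFrame,
    r2_min: float = 0.96,
    raw_mean_min: float = 5.0,
) -> list[str]:
    """Genes with R^2 > r2_min and raw mean > raw_mean_min in every table.

    With several data sets the intersection is taken, mirroring reference
    genes that are stable across cohorts. Sorted by the minimum R^2
    across tables, descending (most robustly linear first).
    """
    if isinstance(stats_tables, pd.DataFrame):
        stats_tables = [stats_tables]
    if not stats_tables:
        raise ValueError("at least one stats table required")
    qualifying: list[pd.Series] = []
    for table in stats_tables:
        if "raw_mean" not in table.columns:
            raise KeyError("stats table lacks a raw_mean column")
        mask = (table["r_squared"] > r2_min) & (table["raw_mean"] > raw_mean_min)
        qualifying.append(table.loc[mask, "r_squared"])
    common = set(qualifying[0].index)
    for q in qualifying[1:]:
        common &= set(q.index)
    min_r2 = {
        g: min(float(q.loc[g]) for q in qualifying) for g in common
    }
    return sorted(common, key=lambda g: (-min_r2[g], g))


def gene_ratio(m: pd.DataFrame, num: str, den: str) -> RatioProfile:
    """Per-sample ratio of two genes and its fold range (max/min).

    The denominator must be strictly positive in every sample; a zero
    raises an error naming the sample.
    """
    for g in (num, den):
        if g not in m.index:
            raise KeyError(f"gene {g!r} not in matrix")
    den_vals = m.loc[den]
    zero = den_vals[den_vals == 0]
    if not zero.empty:
        raise ValueError(
            f"denominator gene {den!r} is zero in sample {zero.index[0]!r}"
        )
    ratios = m.loc[num] / den_vals
    lo, hi = float(ratios.min()), float(ratios.max())
    fold = hi / lo if lo > 0 else np.inf
    return RatioProfile(
        numerator=str(num), denominator=str(den), ratios=ratios,
        min_ratio=lo, max_ratio=hi, fold_range=fold,
        fold_range_display=format_fold_range(fold),
    )
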