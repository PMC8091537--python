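"""Size-factor normalization and Minimum Value Adjustment (MVA) scaling.

Bulk RNA-seq counts span roughly five orders of magnitude across genes,
so raw trendlines are strongly heteroscedastic. MVA divides every gene's
counts by that gene's smallest count, anchoring each trendline at 1 while
preserving within-gene sample order and every scale-free statistic (CV,
skewness, kurtosis, R^2, range ratios).

Two steps live here:

* :func:`median_of_ratios_size_factors` — the DESeq2-style per-sample
  size factors (ratio to the per-gene geometric-mean reference, median
  over genes), used to remove sequencing-depth differences before MVA.
* :func:`mva_scale` — the per-gene minimum-value division.

Genes containing zeros (created by the <0.5 -> 0 floor) have no positive
minimum; they are divided by their smallest *positive* value, the zeros
are kept, and the gene is flagged ``zero_containing`` so downstream
tables can surface or drop it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaledMatrix",
    "median_of_ratios_size_factors",
    "apply_size_factors",
    "mva_scale",
]

ZERO_FLAG = "zero_containing"


@dataclass
class ScaledMatrix:
    """An MVA-scaled matrix together with its audit trail.

    Attributes
    ----------
    values
        Scaled genes x samples matrix; for unflagged genes the row minimum
        is exactly 1.
    mva_divisors
        The per-gene divisor used (the gene minimum, or smallest positive
        value for zero-containing genes).
    size_factors
        Per-sample factors applied before MVA (all 1 if skipped).
    flags
        Per-gene marker strings, e.g. ``zero_containing``.
    """

    values: pd.DataFrame
    mva_divisors: pd.Series
    size_factors: pd.Series | None = None
    flags: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.Series("", index=self.values.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def median_of_ratios_size_factors(m: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For every gene with strictly positive counts in all samples the
    reference is the geometric mean across samples; the size factor of a
    sample is the median over those genes of count/reference.
    """
    values = m.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; filter "
            "low-count genes before size-factor estimation"
        )
    pos = values[all_positive]
    log_ref = np.log(pos).mean(axis=1, keepdims=True)
    ratios = np.log(pos) - log_ref
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.columns, name="size_factor")


def apply_size_factors(m: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's column by its size factor."""
    factors = factors.reindex(m.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    return m.div(factors, axis=1)


def mva_scale(m: pd.DataFrame, size_factors: pd.Series | None = None) -> ScaledMatrix:
    """Minimum Value Adjustment: divide each gene by its smallest count.

    The smallest count of every gene becomes exactly 1, giving all
    trendlines a common starting point. If ``size_factors`` is given the
    matrix is depth-normalized first. A gene whose minimum is 0 is divided
    by its smallest positive value and flagged; an all-zero gene is an
    error (it should have been removed by the low-count filter).
    """
    if size_factors is not None:
        m = apply_size_factors(m, size_factors)
    values = m.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative counts cannot be MVA-scaled")

    all_zero = (values == 0).all(axis=1)
    if all_zero.any():
        raise ValueError(
            f"gene {m.index[np.argmax(all_zero)]!r} is all zeros; apply "
            f"filter_low_counts first"
        )
    with np.errstate(invalid="ignore"):
        masked = np.where(values > 0, values, np.inf)
    divisors = masked.min(axis=1)
    has_zero = (values == 0).any(axis=1)
    scaled = values / divisors[:, None]

    flags = pd.Series(np.where(has_zero, ZERO_FLAG, ""), index=m.index)
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=m.index, columns=m.columns),
        mva_divisors=pd.Series(divisors, index=m.index, name="mva_divisor"),
        size_factors=(
            size_factors
            if size_factors is not None
            else pd.Series(1.0, index=m.columns, name="size_factor")
        ),
        flags=flags,
    )
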