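"""Top-N statistic selection, pairwise correlation and module extraction.

The screen nominates candidate genes two ways: by extreme values of a
tailedness statistic (top-300 lists) and by membership in highly
correlated gene subsets. For ~10^4 genes the full Pearson matrix holds
tens of millions of values, so pair generation is blockwise with an
optional |r| pre-filter: working memory stays bounded by the block size.

Threshold calibration reproduces the manual procedure of tightening a
positive threshold ``hi`` and a negative threshold ``lo`` until the set
of genes participating in at least one extreme pair shrinks to a target
size. Both tails move together along matched empirical quantiles of the
per-gene extreme correlations; the search enumerates those quantile
steps exactly and returns the smallest achievable set >= target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TopList",
    "CorrelationSubset",
    "top_n_by_stat",
    "pairwise_correlation",
    "calibrate_thresholds",
    "extract_cluster",
]


@dataclass
class TopList:
    """Genes holding the N most extreme values of one statistic.

    Ties at the boundary are included, so the list may exceed
    ``n_requested``; ``threshold_value`` is the statistic value of the
    Nth-ranked gene and downstream filters use it inclusively (>=).
    """

    statistic: str
    direction: str
    n_requested: int
    gene_ids: list[str]
    threshold_value: float


@dataclass
class CorrelationSubset:
    """Genes whose extreme pairwise correlations pass (hi, lo) thresholds."""

    hi: float
    lo: float
    selected_genes: list[str]
    pairs: pd.DataFrame = field(repr=False)


def top_n_by_stat(
    stats: pd.DataFrame, stat: str, n: int = 300, direction: str = "largest"
) -> TopList:
    """Rank genes by one statistic and keep the top N (ties included).

    Flagged-infinite values sort above every finite value; NaN (undefined)
    values are never selected. Deterministic under row permutation: within
    ties, genes are ordered by ID.
    """
    if stat not in stats.columns:
        raise KeyError(f"statistic {stat!r} not in table")
    if direction not in ("largest", "smallest"):
        raise ValueError("direction must be 'largest' or 'smallest'")
    col = stats[stat].astype(float)
    col = col[~col.isna()]
    ascending = direction == "smallest"
    ordered = col.iloc[np.lexsort((col.index, col.values if ascending else -col.values))]
    if n > len(ordered):
        logger.warning(
            "requested top %d of %d genes for %s; returning all", n, len(ordered), stat
        )
        n = len(ordered)
    if n == 0:
        return TopList(stat, direction, 0, [], np.nan)
    threshold = float(ordered.iloc[n - 1])
    if ascending:
        keep = ordered[ordered <= threshold]
    else:
        keep = ordered[ordered >= threshold]
    return TopList(stat, direction, n, keep.index.tolist(), threshold)


def _standardize(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
    return centered / norm


def pairwise_correlation(
    m: pd.DataFrame,
    genes: list[str] | None = None,
    r_min_abs: float | None = None,
    block_size: int = 1024,
) -> pd.DataFrame:
    """Pearson r for every unordered gene pair, computed blockwise.

    Constant genes are excluded with a warning (their correlation is
    undefined). ``r_min_abs`` drops pairs with |r| below the bound as each
    block is produced, keeping memory bounded for large matrices.
    Returns a DataFrame with columns ``gene_a``, ``gene_b``, ``r``.
    """
    if m.shape[1] < 3:
        raise ValueError("pairwise correlation needs at least 3 samples")
    if genes is not None:
        m = m.loc[genes]
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        dropped = m.index[sd == 0].tolist()
        logger.warning("excluding %d constant genes from correlation", len(dropped))
        m = m.loc[sd > 0]
        values = values[sd > 0]
    z = _standardize(values)
    ids = m.index.to_numpy()
    out_a, out_b, out_r = [], [], []
    g = len(ids)
    for i0 in range(0, g, block_size):
        zi = z[i0:i0 + block_size]
        for j0 in range(i0, g, block_size):
            block = zi @ z[j0:j0 + block_size].T
            ii, jj = np.meshgrid(
                np.arange(i0, i0 + zi.shape[0]),
                np.arange(j0, j0 + block.shape[1]),
                indexing="ij",
            )
            mask = ii < jj
            if r_min_abs is not None:
                mask &= np.abs(block) >= r_min_abs
            out_a.append(ids[ii[mask]])
            out_b.append(ids[jj[mask]])
            out_r.append(np.clip(block[mask], -1.0, 1.0))
    return pd.DataFrame({
        "gene_a": np.concatenate(out_a) if out_a else [],
        "gene_b": np.concatenate(out_b) if out_b else [],
        "r": np.concatenate(out_r) if out_r else [],
    })


def _extreme_correlations(m: pd.DataFrame, block_size: int = 1024):
    """Per-gene max positive and min negative off-diagonal correlation."""
    values = m.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if not keep.all():
        logger.warning("excluding %d constant genes from calibration",
                       int((~keep).sum()))
    m = m.loc[keep]
    z = _standardize(values[keep])
    g = z.shape[0]
    max_pos = np.full(g, -np.inf)
    min_neg = np.full(g, np.inf)
    for i0 in range(0, g, block_size):
        block = z[i0:i0 + block_size] @ z.T
        rows = np.arange(i0, min(i0 + block_size, g))
        block[np.arange(len(rows)), rows] = np.nan  # mask self-correlation
        block = np.clip(block, -1.0, 1.0)
        max_pos[rows] = np.nanmax(block, axis=1)
        min_neg[rows] = np.nanmin(block, axis=1)
    return m.index, max_pos, min_neg


def calibrate_thresholds(
    m: pd.DataFrame, target_size: int, tail_policy: str = "matched"
) -> CorrelationSubset:
    """Tighten (hi, lo) until the selected gene set is the smallest >= target.

    A gene is selected when its most positive off-diagonal correlation is
    >= hi or its most negative is <= lo. With the default ``matched``
    policy both thresholds slide together along the k-th most extreme
    per-gene values; if a one-tailed step sequence reaches the target with
    a smaller set (e.g. when one tail carries all the structure), that
    set is preferred. ``positive`` or ``negative`` freezes the other tail
    out of play entirely. If the target cannot be reached the closest
    achievable set is returned with a warning.
    """
    if target_size > m.shape[0]:
        raise ValueError("target size exceeds gene count")
    ids, max_pos, min_neg = _extreme_correlations(m)
    g = len(ids)
    eps = 1e-9
    hi_off = float(np.max(max_pos)) + eps   # hi above every r: positive tail off
    lo_off = float(np.min(min_neg)) - eps   # lo below every r: negative tail off
    if target_size == 0:
        return CorrelationSubset(
            hi=hi_off, lo=lo_off,
            selected_genes=[], pairs=pd.DataFrame(columns=["gene_a", "gene_b", "r"]),
        )
    pos_sorted = np.sort(max_pos)[::-1]
    neg_sorted = np.sort(min_neg)
    if tail_policy == "matched":
        # matched quantile steps first; fall back to one-tailed steps so the
        # smallest achievable set is found even when one tail is pure noise
        policies = ("matched", "positive", "negative")
    elif tail_policy in ("positive", "negative"):
        policies = (tail_policy,)
    else:
        raise ValueError(f"unknown tail_policy {tail_policy!r}")

    best = None
    for policy in policies:
        for k in range(1, g + 1):
            hi = pos_sorted[k - 1] if policy in ("matched", "positive") else hi_off
            lo = neg_sorted[k - 1] if policy in ("matched", "negative") else lo_off
            selected = (max_pos >= hi) | (min_neg <= lo)
            size = int(selected.sum())
            if size >= target_size:
                if best is None or size < best[0]:
                    best = (size, hi, lo, selected)
                break
        else:  # tail exhausted without reaching the target
            selected = (max_pos >= (hi_off if policy == "negative" else pos_sorted[-1])) \
                | (min_neg <= (lo_off if policy == "positive" else neg_sorted[-1]))
            size = int(selected.sum())
            if best is None or (best[0] < target_size and size > best[0]):
                best = (size, float(hi_off if policy == "negative" else pos_sorted[-1]),
                        float(lo_off if policy == "positive" else neg_sorted[-1]),
                        selected)
    _, hi, lo, selected = best
    size = int(selected.sum())
    if size < target_size:
        logger.warning(
            "calibration target %d unreachable; closest achievable is %d",
            target_size, size,
        )
    gene_list = ids[selected].tolist()
    pairs = pairwise_correlation(m, genes=gene_list) if gene_list else pd.DataFrame(
        columns=["gene_a", "gene_b", "r"])
    if not pairs.empty:
        pairs = pairs[(pairs["r"] >= hi) | (pairs["r"] <= lo)].reset_index(drop=True)
    return CorrelationSubset(
        hi=float(hi), lo=float(lo), selected_genes=gene_list, pairs=pairs
    )


def extract_cluster(
    m: pd.DataFrame, seed: str, r_min: float, sign: str = "positive"
) -> list[str]:
    """Genes correlated with a seed gene beyond |r_min|, strongest first.

    Emulates seed-based module readout (e.g. the interferon-stimulated
    cluster around IFIT3): returns the seed followed by every gene with
    r(seed, gene) >= r_min (positive sign) or <= -r_min (negative sign),
    ordered by |r| descending with gene-ID tie-break.
    """
    if seed not in m.index:
        raise KeyError(f"seed gene {seed!r} not in matrix")
    seed_vals = m.loc[seed].to_numpy(dtype=float)
    if seed_vals.std() == 0:
        raise ValueError(f"seed gene {seed!r} is constant; correlation undefined")
    others = m.drop(index=seed)
    sd = others.to_numpy(dtype=float).std(axis=1)
    others = others.loc[sd > 0]
    ov = others.to_numpy(dtype=float)
    z_seed = (seed_vals - seed_vals.mean()) / seed_vals.std()
    z = (ov - ov.mean(axis=1, keepdims=True)) / ov.std(axis=1, keepdims=True)
    r = pd.Series((z * z_seed).mean(axis=1), index=others.index).clip(-1.0, 1.0)
    hits = r[r >= r_min] if sign == "positive" else r[r <= -r_min]
    ordered = hits.iloc[np.lexsort((hits.index, -hits.abs().values))]
    return [seed] + ordered.index.tolist()
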