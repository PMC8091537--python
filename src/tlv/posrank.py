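"""Positional ranks and the per-individual gene-collection score.

For every gene the sample with the highest count holds position 1, the
next position 2, and so on (ties broken by sample-ID lexical order). An
individual mounting a coordinated transcriptional response — e.g. an
interferon response to a subclinical infection — holds top positions in
many genes of the responding module at once. The screen exploits this:

1. collect, for each individual, all genes in which that individual
   holds a top position, widening the position cutoff k until at least
   ``min_genes`` (default 1000) genes are collected;
2. intersect the collected genes with the top-300 lists of the
   tailedness statistics (range/median, range/Q3, excess kurtosis,
   Q4 slope ratio), keeping genes at or above each list's threshold;
3. test each filtered list for gene-set over-representation; an
   individual whose best FDR falls at or below a stringent benchmark
   (default 1e-15) is flagged as showing a coordinated response.

Positional ranks are invariant under MVA because per-gene scaling is
monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import TopList, top_n_by_stat
from .enrichment import GeneSetCollection, ora
from .scaling import ScaledMatrix

__all__ = [
    "IndividualGeneList",
    "ScreenConfig",
    "positional_ranks",
    "collect_individual_genes",
    "filter_by_top_thresholds",
    "screen_all_individuals",
]

DEFAULT_SCREEN_STATS = (
    "range_over_median", "range_over_q3", "excess_kurtosis", "ratio_q4",
)


@dataclass
class IndividualGeneList:
    """Genes collected for one individual, before and after filtering."""

    sample_id: str
    rank_cutoff_used: int
    collected_genes: list[str]
    filtered_genes: dict[str, list[str]] = field(default_factory=dict)
    shortfall: bool = False


@dataclass
class ScreenConfig:
    """Knobs of the per-individual screen."""

    min_genes: int = 1000
    top_n: int = 300
    statistics: tuple[str, ...] = DEFAULT_SCREEN_STATS
    fdr_flag: float = 1e-15
    gene_sets: GeneSetCollection | None = None


def positional_ranks(m: pd.DataFrame | ScaledMatrix) -> pd.DataFrame:
    """Per-(gene, sample) integer positions, 1 = highest count per gene.

    Ties go to the lexically smaller sample ID, making every row a
    deterministic permutation of 1..n_samples.
    """
    df = m.values if isinstance(m, ScaledMatrix) else m
    if df.empty:
        raise ValueError("empty matrix")
    cols = df.columns.astype(str)
    col_order = np.argsort(cols)  # lexical tie-break
    values = df.to_numpy(dtype=float)[:, col_order]
    # sort descending by value, stable over lexically ordered columns
    order = np.argsort(-values, axis=1, kind="stable")
    positions = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    positions[rows, order] = np.arange(1, values.shape[1] + 1)
    out = pd.DataFrame(positions, index=df.index, columns=cols[col_order])
    return out[df.columns.astype(str)]


def collect_individual_genes(
    prt: pd.DataFrame, sample: str, min_genes: int = 1000
) -> IndividualGeneList:
    """Widen the position cutoff until >= min_genes genes are collected.

    Starting at k=1, genes where the sample holds position <= k are
    collected; k grows until the requested count is reached or k equals
    the number of samples (shortfall flagged).
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    pos = prt[sample].to_numpy()
    n = prt.shape[1]
    counts = np.bincount(pos, minlength=n + 1).cumsum()
    reached = np.nonzero(counts[1:] >= min_genes)[0]
    k = int(reached[0]) + 1 if len(reached) else n
    collected = prt.index[pos <= k].tolist()
    return IndividualGeneList(
        sample_id=str(sample),
        rank_cutoff_used=k,
        collected_genes=collected,
        shortfall=len(collected) < min_genes,
    )


def filter_by_top_thresholds(
    igl: IndividualGeneList,
    stats: pd.DataFrame,
    top_lists: dict[str, TopList],
) -> IndividualGeneList:
    """Keep collected genes at or above each statistic's top-N threshold.

    The comparison is inclusive (>=), matching the rule that a gene
    qualifies when its value reaches the value of the Nth-ranked gene.
    Flagged-infinite values qualify; undefined (NaN) values do not.
    """
    for stat in top_lists:
        if stat not in stats.columns:
            raise KeyError(f"statistic {stat!r} missing from stats table")
    collected = [g for g in igl.collected_genes if g in stats.index]
    filtered: dict[str, list[str]] = {}
    for stat, top in top_lists.items():
        vals = stats.loc[collected, stat].astype(float)
        if top.direction == "largest":
            keep = vals[vals >= top.threshold_value]
        else:
            keep = vals[vals <= top.threshold_value]
        filtered[stat] = keep.index.tolist()
    igl.filtered_genes = filtered
    return igl


def screen_all_individuals(
    m: pd.DataFrame | ScaledMatrix,
    stats: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the positional-rank screen for every sample.

    Returns one row per individual with the cutoff used, collected and
    filtered gene counts, and — when a gene-set collection is supplied —
    the best enrichment FDR over the per-statistic filtered lists plus a
    ``flagged`` boolean (best FDR <= config.fdr_flag).
    """
    config = config or ScreenConfig()
    df = m.values if isinstance(m, ScaledMatrix) else m
    prt = positional_ranks(df)
    top_lists = {
        s: top_n_by_stat(stats, s, n=config.top_n) for s in config.statistics
    }
    rows = []
    gene_lists: dict[str, IndividualGeneList] = {}
    for sample in df.columns:
        igl = collect_individual_genes(prt, sample, config.min_genes)
        igl = filter_by_top_thresholds(igl, stats, top_lists)
        gene_lists[str(sample)] = igl
        row = {
            "sample_id": str(sample),
            "rank_cutoff_used": igl.rank_cutoff_used,
            "n_collected": len(igl.collected_genes),
            "shortfall": igl.shortfall,
        }
        for stat in config.statistics:
            row[f"n_{stat}"] = len(igl.filtered_genes[stat])
        if config.gene_sets is not None:
            best_fdr, best_set, best_stat = np.inf, "", ""
            for stat, genes in igl.filtered_genes.items():
                if not genes:
                    continue
                res = ora(genes, config.gene_sets)
                if not res.empty and res["fdr"].iloc[0] < best_fdr:
                    best_fdr = float(res["fdr"].iloc[0])
                    best_set = str(res["set"].iloc[0])
                    best_stat = stat
            row["best_fdr"] = best_fdr
            row["best_set"] = best_set
            row["best_statistic"] = best_stat
            row["flagged"] = best_fdr <= config.fdr_flag
        rows.append(row)
    report = pd.DataFrame(rows).set_index("sample_id")
    report.attrs["gene_lists"] = gene_lists
    report.attrs["top_lists"] = top_lists
    return report
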