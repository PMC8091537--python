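"""Reading, writing and filtering of gene x sample count matrices.

A count matrix is represented throughout the package as a
:class:`pandas.DataFrame` whose index holds gene identifiers (rows) and whose
columns hold sample identifiers. Values are non-negative floats on a
TPM-like normalized-count scale.

The filtering operations implement the pre-processing applied to
whole-blood RNA-seq control data before trendline analysis:

1. restrict the matrix to protein-coding genes (everything else goes to a
   "discard" matrix kept for audit),
2. merge rows of a gene reported at multiple genomic locations (CNV
   aliases) into a single row by element-wise summation,
3. replace values below a floor (default 0.5 counts) with 0 and then drop
   genes whose post-replacement mean falls below a minimum (default 0.5).

The replacement-before-mean order matters and is pinned by tests: a gene
such as ``[0.3, 0.6, 0.7]`` is removed (mean after flooring 0.433 < 0.5)
even though its raw mean is 0.533.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "LowCountFilterResult",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_list",
    "read_alias_map",
    "filter_protein_coding",
    "merge_cnv",
    "filter_low_counts",
]


@dataclass
class GeneAnnotation:
    """Protein-coding gene universe and CNV alias map.

    Parameters
    ----------
    protein_coding
        Symbols of protein-coding genes; genes outside this set are
        discarded by :func:`filter_protein_coding`.
    cnv_aliases
        Map from a location-suffixed symbol (e.g. ``GENE1_loc2``) to the
        canonical symbol under which its counts are combined. One level
        only: alias targets must not themselves be aliases.
    """

    protein_coding: set[str] = field(default_factory=set)
    cnv_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.cnv_aliases.items():
            if dst in self.cnv_aliases and self.cnv_aliases[dst] != dst:
                raise ValueError(
                    f"alias map is not one-level: {src!r} -> {dst!r} but "
                    f"{dst!r} is itself an alias"
                )


@dataclass
class LowCountFilterResult:
    """Outcome of :func:`filter_low_counts`: the kept matrix plus a report."""

    matrix: pd.DataFrame
    removed_genes: list[str]
    n_values_floored: int


def _validate_matrix(df: pd.DataFrame, source: str = "count matrix") -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicate gene IDs {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicate sample IDs {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: non-numeric cell encountered ({exc})") from exc
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{source}: non-numeric or missing cell at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{source}: negative value {values[g, s]} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    out = df.astype(float)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_count_matrix(
    path, sep: str = "\t", transpose: bool = False
) -> pd.DataFrame:
    """Read a TSV/CSV count matrix (column 1 = gene ID, header = sample IDs).

    With ``transpose=True`` the file is interpreted as samples-as-rows and
    transposed to the genes-as-rows convention. Non-numeric or negative
    cells raise ``ValueError`` naming the offending gene and sample.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample IDs {dups[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = "gene_id"
    if transpose:
        df = df.T
        df.index.name = "gene_id"
    return _validate_matrix(df, source=str(path))


def write_count_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a count matrix in the same genes x samples TSV layout."""
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, '#' comments."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def read_alias_map(path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column TSV mapping location-suffixed symbol -> canonical."""
    table = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: alias map needs two columns")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def filter_protein_coding(
    m: pd.DataFrame, ann: GeneAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a matrix into (protein-coding, discarded) row subsets.

    Mirrors the pre-processing step that removes noncoding transcripts to a
    separate discard sheet before pathway analysis.
    """
    if not ann.protein_coding:
        raise ValueError("protein-coding annotation is empty")
    keep_mask = m.index.isin(ann.protein_coding)
    kept = m.loc[keep_mask]
    discarded = m.loc[~keep_mask]
    if kept.empty:
        logger.warning(
            "no matrix gene is in the protein-coding list; kept matrix is empty"
        )
    return kept, discarded


def merge_cnv(m: pd.DataFrame, ann: GeneAnnotation) -> pd.DataFrame:
    """Combine rows of multi-location genes under their canonical symbol.

    Rows whose IDs appear in the alias map are summed element-wise into a
    single row under the canonical symbol; the merged row takes the
    position of the first contributing row. Total counts are conserved.
    An alias whose target collides with an unrelated pre-existing gene row
    is an error.
    """
    aliases = {k: v for k, v in ann.cnv_aliases.items() if k in m.index}
    if not aliases:
        return m.copy()
    existing = set(m.index)
    for dst in set(aliases.values()):
        # A pre-existing row under the canonical symbol is only mergeable if
        # the alias map declares it a contributor (self-alias dst -> dst);
        # otherwise it is an unrelated gene that happens to share the name.
        if dst in existing and ann.cnv_aliases.get(dst) != dst:
            raise ValueError(
                f"alias target {dst!r} collides with an existing, un-aliased "
                f"gene row"
            )

    canonical = pd.Series(
        [aliases.get(g, g) for g in m.index], index=m.index, name="canonical"
    )
    merged = m.groupby(canonical, sort=False).sum()
    merged.index.name = m.index.name
    return _validate_matrix(merged, source="merged matrix")


def filter_low_counts(
    m: pd.DataFrame, floor: float = 0.5, mean_min: float = 0.5
) -> LowCountFilterResult:
    """Floor sub-threshold values to 0, then drop low-mean genes.

    Every value strictly below ``floor`` is replaced with 0 FIRST; genes
    whose post-replacement mean is strictly below ``mean_min`` are then
    removed. Applying the filter twice equals applying it once.
    """
    if floor < 0 or mean_min < 0:
        raise ValueError("floor and mean_min must be non-negative")
    values = m.to_numpy(dtype=float)
    floored = np.where(values < floor, 0.0, values)
    n_floored = int((floored != values).sum())
    keep = floored.mean(axis=1) >= mean_min
    kept = pd.DataFrame(
        floored[keep], index=m.index[keep], columns=m.columns
    )
    removed = m.index[~keep].tolist()
    if kept.empty:
        logger.warning("low-count filter removed every gene")
    if removed:
        logger.info(
            "low-count filter removed %d genes (floor=%g, mean_min=%g)",
            len(removed), floor, mean_min,
        )
    return LowCountFilterResult(kept, removed, n_floored)
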