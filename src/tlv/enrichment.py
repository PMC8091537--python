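"""Local gene-set over-representation analysis (hypergeometric + BH FDR).

A query gene list is tested against each set of a GMT collection with
the hypergeometric upper tail: with N background genes, K of them in
the set and a query of n genes overlapping the set in k,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

and p-values are adjusted across sets with Benjamini–Hochberg. The
background universe is the analyzed gene space (post-filter
protein-coding genes restricted to the annotation), not the whole
genome — restricting the universe to coding genes is what makes the
screen's FDRs sensitive in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "bh_fdr",
    "ora",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Sets are restricted to the background on construction and empty sets
    are dropped, so every remaining set can contribute a valid
    hypergeometric test.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        restricted = {}
        for name, genes in self.sets.items():
            inter = frozenset(genes) & self.background
            if inter:
                restricted[name] = inter
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, background: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes; tab-separated).

    Duplicate genes within a set are deduplicated. If no background is
    given, the union of all set genes is used.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene)"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    universe = background if background is not None else set().union(*sets.values())
    return GeneSetCollection(sets=sets, background=frozenset(universe),
                             descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (genes sorted for determinism)."""
    with open(path, "w") as fh:
        for name in sorted(gsc.sets):
            desc = gsc.descriptions.get(name, "")
            genes = "\t".join(sorted(gsc.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query: list[str], gsc: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against every set.

    The query is restricted to the background first; p = P(X >= k) per
    set, BH-adjusted across sets, sorted by FDR then p then name.
    Columns: set, K (set size), n (query size), k (overlap), p, fdr.
    """
    if not query:
        raise ValueError("empty query gene list")
    q = frozenset(query) & gsc.background
    N = len(gsc.background)
    n = len(q)
    if n == 0:
        raise ValueError("no query gene is in the background universe")
    names = sorted(gsc.sets)
    K = np.array([len(gsc.sets[name]) for name in names])
    k = np.array([len(gsc.sets[name] & q) for name in names])
    p = hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "set": names, "K": K, "n": n, "k": k, "p": p, "fdr": bh_fdr(p),
    })
    return table.sort_values(["fdr", "p", "set"]).reset_index(drop=True)
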