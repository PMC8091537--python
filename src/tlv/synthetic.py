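"""Synthetic count matrices with the structure the screen assumes.

The generator emulates a whole-blood control cohort:

* **baseline genes** — per-gene mean drawn log-uniformly over five
  decades of expression; counts are normal around that mean with a
  common coefficient of variation (~0.2), truncated at zero. Rank-
  ordered draws from such a distribution produce the near-linear
  "control envelope" trendlines that dominate real control data.
* **a tailed module** — a small block of genes (default 14, the size of
  the interferon-stimulated cluster) jointly elevated in a few affected
  individuals (default 4 of 35) by per-(gene, sample) fold factors
  drawn log-uniformly from 5–50x. These genes produce the steep final
  quartile the tailedness statistics target, and the affected samples
  hold the top positional ranks of every module gene.
* **bimodal sex-linked genes** — two-level genes high in a fixed block
  of samples (default the last 11, mirroring the males of a mixed
  cohort) and near-silent elsewhere.

Ground-truth labels for every group are returned alongside the matrix
so recovery can be measured exactly. Generation is bit-for-bit
reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "spike_in_reference",
    "truth_gene_sets",
]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a 35-sample control cohort."""

    n_samples: int = 35
    n_genes: int = 8746
    seed: int = 0
    mean_log10_range: tuple[float, float] = (0.0, 5.0)
    baseline_cv: float = 0.2
    tailed_n_genes: int = 14
    tailed_affected: int | list[str] = 4
    tailed_fold_range: tuple[float, float] = (5.0, 50.0)
    bimodal_count: int = 20
    bimodal_high_group_size: int = 11
    bimodal_low_level: float = 0.05
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 samples and 1 gene")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        lo, hi = self.tailed_fold_range
        if lo <= 1 or hi < lo:
            raise ValueError("tailed folds must exceed 1 and be ordered")
        n_special = self.tailed_n_genes + self.bimodal_count
        if n_special > self.n_genes:
            raise ValueError("more special genes than genes")
        n_aff = (self.tailed_affected if isinstance(self.tailed_affected, int)
                 else len(self.tailed_affected))
        if n_aff > self.n_samples:
            raise ValueError("more affected samples than samples")
        if self.bimodal_high_group_size > self.n_samples:
            raise ValueError("bimodal high group larger than cohort")


@dataclass
class GroundTruth:
    """Labels of the generated gene and sample groups."""

    linear_gene_ids: list[str] = field(default_factory=list)
    tailed_gene_ids: list[str] = field(default_factory=list)
    bimodal_gene_ids: list[str] = field(default_factory=list)
    affected_sample_ids: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "GroundTruth":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a count matrix plus ground-truth labels under ``config``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = _ids("GENE", cfg.n_genes, 5)
    samples = _ids("S", cfg.n_samples, 2)

    lo10, hi10 = cfg.mean_log10_range
    mu = 10.0 ** rng.uniform(lo10, hi10, size=cfg.n_genes)
    values = rng.normal(mu[:, None], cfg.baseline_cv * mu[:, None],
                        size=(cfg.n_genes, cfg.n_samples))
    values = np.clip(values, 0.0, None)

    special = rng.choice(cfg.n_genes, size=cfg.tailed_n_genes + cfg.bimodal_count,
                         replace=False)
    tailed_idx = special[:cfg.tailed_n_genes]
    bimodal_idx = special[cfg.tailed_n_genes:]

    if isinstance(cfg.tailed_affected, int):
        affected_idx = np.sort(
            rng.choice(cfg.n_samples, size=cfg.tailed_affected, replace=False))
    else:
        affected_idx = np.array([samples.index(s) for s in cfg.tailed_affected])
    if len(tailed_idx) and len(affected_idx):
        flo, fhi = cfg.tailed_fold_range
        folds = np.exp(rng.uniform(np.log(flo), np.log(fhi),
                                   size=(len(tailed_idx), len(affected_idx))))
        values[np.ix_(tailed_idx, affected_idx)] *= folds

    if len(bimodal_idx):
        high = np.arange(cfg.n_samples - cfg.bimodal_high_group_size, cfg.n_samples)
        low = np.setdiff1d(np.arange(cfg.n_samples), high)
        low_mu = cfg.bimodal_low_level * mu[bimodal_idx]
        values[np.ix_(bimodal_idx, low)] = np.clip(
            rng.normal(low_mu[:, None], cfg.baseline_cv * low_mu[:, None],
                       size=(len(bimodal_idx), len(low))), 0.0, None)

    if cfg.zero_inflation > 0:
        mask = rng.random(values.shape) < cfg.zero_inflation
        values[mask] = 0.0

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene_id"
    special_set = set(special.tolist())
    truth = GroundTruth(
        linear_gene_ids=[g for i, g in enumerate(genes) if i not in special_set],
        tailed_gene_ids=[genes[i] for i in tailed_idx],
        bimodal_gene_ids=[genes[i] for i in bimodal_idx],
        affected_sample_ids=[samples[i] for i in affected_idx],
    )
    return matrix, truth


def spike_in_reference(
    n_controls: int = 4,
    n_samples: int = 35,
    noise_cv: float = 0.02,
    aberrant_sample: str | None = None,
    aberrant_fold: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """External-control-like rows: constant concentration + technical noise.

    Emulates ERCC spike-in standards, optionally with one aberrant sample
    whose controls are uniformly elevated (a sample-processing artifact).
    With ``noise_cv=0`` the rows are exactly constant.
    """
    rng = np.random.default_rng(seed)
    samples = _ids("S", n_samples, 2)
    levels = 10.0 ** np.linspace(1, 4, n_controls)
    values = levels[:, None] * (
        1.0 + noise_cv * rng.standard_normal((n_controls, n_samples)))
    values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=_ids("ERCC-", n_controls, 3), columns=samples)
    df.index.name = "gene_id"
    if aberrant_sample is not None:
        if aberrant_sample not in df.columns:
            raise KeyError(f"sample {aberrant_sample!r} not in matrix")
        df[aberrant_sample] *= aberrant_fold
    return df


def truth_gene_sets(
    truth: GroundTruth,
    background: list[str],
    n_decoy_sets: int = 20,
    decoy_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic pathway collection: the true tailed module plus decoys.

    Stands in for a pathway database in tests: one set holds the
    ground-truth tailed module ("the responding pathway"), the decoys are
    random draws from the background. Enrichment of an individual's
    filtered genes in the module set is then the detectable signal.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {
        "TAILED_MODULE": frozenset(truth.tailed_gene_ids)
    }
    bg = np.asarray(background)
    for i in range(n_decoy_sets):
        members = rng.choice(bg, size=min(decoy_size, len(bg)), replace=False)
        sets[f"DECOY_{i:02d}"] = frozenset(members.tolist())
    return GeneSetCollection(sets=sets, background=frozenset(background))
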