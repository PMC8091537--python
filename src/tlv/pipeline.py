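"""One-command orchestration: filter -> scale -> stats -> select -> screen.

The pipeline strings the library stages together with fixed artifact
names so a run is auditable and byte-reproducible under a fixed config:

    kept.tsv / discard.tsv     protein-coding split, low counts removed
    mva.tsv / divisors.tsv     MVA-scaled matrix and per-gene divisors
    size_factors.tsv           per-sample median-of-ratios factors
    stats.tsv                  trendline statistics table
    top_<stat>.txt             top-N gene lists per tailedness statistic
    screen.tsv                 per-individual positional-rank screen
    individuals/<sample>/<stat>.txt   filtered gene lists (paste-ready)
    enrichment_<sample>.tsv    per-individual ORA tables (if GMT given)
    report.json                machine-readable summary

Every threshold in effect is echoed into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import matrix_io, scaling
from .enrichment import GeneSetCollection, ora, read_gmt
from .posrank import ScreenConfig, screen_all_individuals
from .trendline import stats_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a full screen run."""

    counts: str = ""
    coding_list: str | None = None
    aliases: str | None = None
    gmt: str | None = None
    out_dir: str = "tlv_out"
    floor: float = 0.5
    mean_min: float = 0.5
    top_n: int = 300
    min_genes: int = 1000
    fdr_flag: float = 1e-15
    size_factors: bool = True
    transpose: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
) -> dict:
    """Execute the screen end to end, writing artifacts under out_dir.

    ``counts`` may be passed in memory (e.g. from the synthetic
    generator); otherwise it is read from ``config.counts``. Returns the
    report dictionary also written to ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        if counts is None:
            counts = matrix_io.read_count_matrix(
                config.counts, transpose=config.transpose)

        stage = "filter"
        ann = matrix_io.GeneAnnotation(
            protein_coding=(
                set(matrix_io.read_gene_list(config.coding_list))
                if config.coding_list else set(counts.index)
            ),
            cnv_aliases=(
                matrix_io.read_alias_map(config.aliases) if config.aliases else {}
            ),
        )
        kept, discarded = matrix_io.filter_protein_coding(counts, ann)
        kept = matrix_io.merge_cnv(kept, ann)
        low = matrix_io.filter_low_counts(kept, config.floor, config.mean_min)
        kept = low.matrix
        matrix_io.write_count_matrix(kept, out / "kept.tsv")
        matrix_io.write_count_matrix(discarded, out / "discard.tsv")

        stage = "scale"
        factors = (scaling.median_of_ratios_size_factors(kept)
                   if config.size_factors else None)
        scaled = scaling.mva_scale(kept, size_factors=factors)
        matrix_io.write_count_matrix(scaled.values, out / "mva.tsv")
        scaled.mva_divisors.to_csv(out / "divisors.tsv", sep="\t")
        scaled.size_factors.to_csv(out / "size_factors.tsv", sep="\t")

        stage = "stats"
        stats = stats_table(scaled, raw=kept)
        stats.to_csv(out / "stats.tsv", sep="\t")

        stage = "screen"
        gsc: GeneSetCollection | None = None
        if config.gmt:
            gsc = read_gmt(config.gmt, background=set(kept.index))
        screen_cfg = ScreenConfig(
            min_genes=config.min_genes, top_n=config.top_n,
            fdr_flag=config.fdr_flag, gene_sets=gsc,
        )
        report_df = screen_all_individuals(scaled, stats, screen_cfg)
        report_df.drop(columns=[], errors="ignore").to_csv(
            out / "screen.tsv", sep="\t")

        for stat, top in report_df.attrs["top_lists"].items():
            (out / f"top_{stat}.txt").write_text(
                "\n".join(top.gene_ids) + "\n")
        for sample, igl in report_df.attrs["gene_lists"].items():
            sdir = out / "individuals" / sample
            sdir.mkdir(parents=True, exist_ok=True)
            for stat, genes in igl.filtered_genes.items():
                (sdir / f"{stat}.txt").write_text(
                    "\n".join(genes) + ("\n" if genes else ""))
        if gsc is not None:
            for sample, igl in report_df.attrs["gene_lists"].items():
                frames = []
                for stat, genes in igl.filtered_genes.items():
                    if genes:
                        res = ora(genes, gsc)
                        res.insert(0, "statistic", stat)
                        frames.append(res)
                if frames:
                    pd.concat(frames).to_csv(
                        out / f"enrichment_{sample}.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    flagged = (report_df.index[report_df["flagged"]].tolist()
               if "flagged" in report_df.columns else [])
    report = {
        "config": asdict(config),
        "n_genes_input": int(counts.shape[0]),
        "n_genes_retained": int(kept.shape[0]),
        "n_genes_discarded_noncoding": int(discarded.shape[0]),
        "n_genes_removed_low_count": len(low.removed_genes),
        "n_samples": int(kept.shape[1]),
        "top_lists": {
            stat: {"threshold_value": top.threshold_value, "n_genes": len(top.gene_ids)}
            for stat, top in report_df.attrs["top_lists"].items()
        },
        "flagged_individuals": flagged,
        "screen": json.loads(
            report_df.drop(columns=["best_set", "best_statistic"], errors="ignore")
            .replace([float("inf")], None).to_json(orient="index")),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
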