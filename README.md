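# tlv — trendline variability screen for RNA-seq count matrices

`tlv` detects **intra-group biological variability** in bulk RNA-seq data
*before* differential expression: individuals inside a nominally homogeneous
group (e.g. healthy controls) who are mounting a coordinated transcriptional
response — such as an interferon response to a subclinical infection — and
the gene modules driving it. Standard DE tools treat such samples as
unexplained outliers; this screen names the individuals, the genes and the
pathways.

## The method

Starting from a gene × sample matrix of normalized counts (TPM-like):

1. **Filter.** Keep protein-coding genes, merge multi-location (CNV) rows
   by summation, replace counts < 0.5 with 0, then drop genes whose
   post-replacement mean is < 0.5.
2. **Scale.** Optional median-of-ratios size factors, then **Minimum Value
   Adjustment (MVA)**: each gene's counts are divided by that gene's
   smallest count,

   ```
   MVA_g(s) = x_g(s) / min_s x_g(s)
   ```

   so every gene's trendline starts at 1. Counts spanning ~5 log10 across
   genes become directly comparable, while every within-gene shape
   statistic (CV, skewness, kurtosis, R², range ratios) is untouched.
3. **Trendlines.** Sort each gene's counts ascending over the n samples
   and regress value on rank 1..n. Genes drawing from a common
   within-group distribution give near-linear trendlines (R² ≥ 0.9);
   "tailed" genes bend upward in the final quartile. Tailedness is scored
   by CV, max/min, range/median, range/Q3, skewness, excess kurtosis, R²,
   and quartile-segment slope ratios Q1/(Q2+Q3) and Q4/(Q2+Q3).
4. **Select.** Top-300 gene lists per statistic (ties included), pairwise
   Pearson correlation with threshold calibration to a target subset size,
   and seed-gene cluster extraction.
5. **Attribute.** Positional ranks (position 1 = the sample with the
   highest count for that gene); for each individual, collect ≥ 1000 genes
   in which that individual holds top positions, intersect with the
   top-300 tailedness lists, and test the result for gene-set
   over-representation (hypergeometric + Benjamini–Hochberg). Individuals
   whose best FDR ≤ 1e-15 are flagged as showing a coordinated response.
6. **Cross-check.** Stable reference genes (R² > 0.96, raw mean > 5) and
   per-sample gene-expression ratios: fold ranges far above the ~2×
   technical envelope, concentrated in the flagged individuals, confirm
   the response is biological.

A synthetic-data generator produces cohorts with this exact structure —
a linear control envelope across five decades of expression, a
coordinated tailed module elevated 5–50× in a few individuals, bimodal
sex-linked genes — together with ground-truth labels, so every stage is
testable without any download.

## Worked example

```python
import tlv
from tlv.synthetic import SyntheticConfig, generate, truth_gene_sets

cfg = SyntheticConfig(n_genes=2000, seed=11)      # 35 samples, 4 affected
counts, truth = generate(cfg)

kept = tlv.filter_low_counts(counts).matrix
scaled = tlv.mva_scale(kept, size_factors=tlv.median_of_ratios_size_factors(kept))
stats = tlv.stats_table(scaled, raw=kept)

top = tlv.top_n_by_stat(stats, "range_over_q3", n=300)
gsc = truth_gene_sets(truth, list(kept.index), seed=11)
report = tlv.screen_all_individuals(
    scaled, stats, tlv.ScreenConfig(min_genes=300, gene_sets=gsc))
print(report[report.flagged][["rank_cutoff_used", "n_collected", "best_fdr"]])
```

prints

```
genes retained: 1998
linear fraction (R^2 >= 0.9): 87.4%
spiked module genes in top-300 by range/Q3: 14 of 14
flagged individuals: S22, S24, S31, S34
           rank_cutoff_used  n_collected      best_fdr
sample_id
S22                       6          326  2.851324e-22
S24                       6          337  4.052185e-23
S31                       5          311  1.112365e-22
S34                       6          358  4.434447e-21
truly affected:    S22, S24, S31, S34
```

87% of genes fall in the linear control envelope; all 14 spiked module
genes land in the top-300 by range/Q3; the positional-rank screen flags
exactly the four affected individuals (best enrichment FDRs around
1e-21 to 1e-23, far below the 1e-15 benchmark) with no false positives.

The same pipeline runs from the shell:

```bash
tlv simulate --config sim.yaml --out counts.tsv --truth truth.json
tlv run --counts counts.tsv --gmt sets.gmt --out-dir out/
tlv ratios --counts out/kept.tsv --num GENE00042 --den GENE00007
```

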