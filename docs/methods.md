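# Methods

## Model of the data

The screen assumes a gene × sample matrix of depth-normalized,
non-negative counts (TPM-like) for a *single* group of n samples
(n = 35 by default; n ≥ 16 recommended for the quartile-slope
statistics). Within the group, the counts of a "well-behaved" gene are
modelled as independent draws from a common unimodal distribution with
mean-proportional noise — approximately Normal(μ_g, (cv·μ_g)²) with a
coefficient of variation cv around 0.2. Rank-ordering such draws yields
a nearly linear "trendline" (the empirical quantile function of a
normal is close to linear over the central body), which is why linear
trendlines with R² ≥ 0.9 are treated as the *control envelope*:
variation compatible with sampling noise.

Departures of interest are genes whose trendline bends sharply in the
last (or first) quartile — a few samples far above the envelope. When
many such genes bend for the *same* samples, the screen attributes the
tail to those individuals and asks whether the gene set is enriched for
a coherent biological pathway.

## Pipeline stages and their parameters

**Filtering** (`matrix_io`). Counts below `floor = 0.5` are set to 0
*first*; genes with post-replacement mean below `mean_min = 0.5` are
then removed. The order matters (a gene at [0.3, 0.6, 0.7] is removed;
reversing the order would keep it) and is pinned by test. CNV/multi-
location rows are merged by element-wise **sum**, which conserves total
library signal; the protein-coding filter runs before the merge by
default (both orders are available, the result differs only for
noncoding aliases).

**Scaling** (`scaling`). Optional median-of-ratios size factors
(geometric-mean reference over genes positive in all samples; per-sample
median of count/reference) remove residual depth differences; they are
optional because archived TPM matrices are often already normalized.
MVA divides each gene by its smallest count, so the smallest value of
every gene becomes exactly 1. For genes containing zeros (created by
the floor) the minimum is 0 and the formula is undefined; the divisor
falls back to the smallest *positive* value, zeros are kept, and the
gene carries a `zero_containing` flag through all downstream tables, so
either treatment (keep or drop) is recoverable. MVA is a positive
per-gene rescaling: it preserves within-gene sample order and leaves
CV, skewness, kurtosis, R², max/min, range/median, range/Q3 and the
quartile-slope ratios bit-identical, which the suite asserts.

**Trendline statistics** (`trendline`). Percentiles use the inclusive
plotting-position convention h = p(n−1)+1 (the spreadsheet
QUARTILE.INC / numpy default), and skewness/kurtosis use the
bias-corrected spreadsheet formulas (scipy `bias=False`), matching the
tooling the method was developed with; both conventions are pinned by
independent direct-formula oracles at 1e-10 relative tolerance. The
rank regressor is 1..n, so slopes are counts per rank step. Quartile
segments take round(n/4) ranks at each end (implemented as
floor(n/4 + 0.5) to avoid banker's rounding; 35 → 9/17/9, 16 → 4/8/4);
each segment needs ≥ 2 points. Degenerate inputs are kept and flagged
rather than dropped: constant genes report sd = cv = slope = 0 and
R² = 0 (`constant` flag); zero median or zero minimum with nonzero
range makes range/median or max/min infinite (`inf_*` flags).
Flagged-infinite values deliberately sort *above* all finite values in
top-N selection; NaN (undefined, e.g. kurtosis at n < 4) never
qualifies.

**Selection** (`correlation`). Top-N lists (default N = 300) include
boundary ties, so a list can exceed N; downstream filters use the Nth
value inclusively (≥). Pairwise Pearson correlation is computed
blockwise on standardized rows with an optional |r| pre-filter, keeping
working memory bounded for ~10⁴ genes. Threshold calibration selects
genes participating in at least one pair with r ≥ hi or r ≤ −lo tails:
both thresholds slide along matched per-tail empirical quantile steps
(k-th most extreme per-gene max-positive / min-negative correlation),
and one-tailed step sequences are also searched so that when one tail
carries all the structure the smallest achievable set ≥ target is still
found. The search space is a finite grid, so exact enumeration replaces
bisection; selected-set size is monotone along each sequence by
construction.

**Positional-rank screen** (`posrank`). Position 1 = highest count per
gene, ties to the lexically smaller sample ID. Per individual, the
cutoff k grows from 1 until at least `min_genes = 1000` genes have that
individual at position ≤ k (the minimal reading of "collect ≥ 1000
top-positioned genes"; the operation is isolated so alternative scoring
rules can be swapped in). The collected genes are intersected with the
top-300 lists of range/median, range/Q3, excess kurtosis and the Q4
slope ratio, and each filtered list is tested by ORA; an individual is
flagged when its best FDR ≤ `fdr_flag = 1e-15`, a deliberately
stringent benchmark: coordinated modules of ~14 genes inside filtered
lists of tens of genes give FDRs many orders below it, while the best
decoy enrichments in unaffected individuals sit near 1e-2.

**Enrichment** (`enrichment`). Hypergeometric upper tail
p = P(X ≥ k) with BH adjustment across sets. The background universe is
the analyzed (post-filter) gene space restricted to the annotation, not
the whole genome — the restriction is what gives the screen its FDR
sensitivity. The screen does not attempt to match any external
enrichment service's proprietary FDR machinery; agreement is expected
to be qualitative.

**Reference ratios** (`ratios`). Stable-gene candidates require
R² > 0.96 *and* raw mean > 5 (strict inequalities, defaults not
hard-coded); across multiple cohorts the intersection is taken.
Fold ranges are reported raw and with presentation rounding (nearest
integer at ≥ 10, one decimal below, halves up), matching how such
ranges are conventionally printed.

## The synthetic cohort

`synthetic.generate` draws, per gene, μ_g log-uniform over 10⁰–10⁵ and
counts Normal(μ_g, 0.2·μ_g) truncated at 0 — the control envelope. A
14-gene tailed module is multiplied by per-(gene, sample) factors
log-uniform on [5, 50] in 4 randomly chosen affected samples,
emulating a coordinated but variable response module. Twenty bimodal
genes (a realistic count of detectably sex-linked transcripts in whole
blood) are high in the last 11 samples and at 5 % of that level
elsewhere, reproducing the two-level trendlines of Y-linked genes in a
mixed-sex cohort of 24 + 11. Zero inflation defaults to 0. ERCC-like
spike-in rows (constant concentration, 2 % technical CV, optional
single aberrant sample) are available separately.

What the generator does *not* emulate: library-size/negative-binomial
overdispersion structure, gene–gene baseline correlation (decoy genes
are independent), mean–variance trends beyond a constant CV, and batch
effects. Passing the recovery tests therefore demonstrates that the
screen's machinery is correct and sensitive under its own model
assumptions — not that real cohorts will show the same flagging rate.
Under these conditions the linear-envelope fraction measures ~87–89 %,
somewhat above the 65–70 % seen in real control cohorts, because real
data contain additional dispersion sources the baseline model omits.

## Problem sizes and determinism

The test suite uses reduced cohorts (500–2000 genes) for module-level
tests and the full default conditions (8746 genes × 35 samples,
20 seeds) for the end-to-end recovery checks; the whole suite runs in
well under a minute on one CPU because the statistics are vectorized
across genes. All randomness flows through `numpy.random.default_rng`
seeds carried in the configuration objects; identical seeds give
bit-identical matrices, reports and artifacts.

## Known limitations

- The screen is descriptive, not inferential: no p-value is attached to
  "this individual diverges", only to the gene-set overlap of its
  collected genes.
- Tailedness statistics respond to any heavy-tailed structure, including
  technical artifacts confined to one sample; the spike-in and
  gene-ratio cross-checks exist to separate those.
- Correlation-threshold calibration reproduces a target subset *size*;
  specific published threshold values depend on the original data and
  are not recoverable from the contract.
- With fewer than ~16 samples the quartile-slope statistics are
  unstable (2–3 points per end segment) and kurtosis is noisy; the
  screen still runs but those columns should be read with caution.
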