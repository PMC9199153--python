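# Methods

## Problem setting

A paired ribosome-profiling / RNA-seq experiment measures, per gene and
condition, both mRNA abundance and ribosome-footprint abundance. Translation
efficiency (TE) is their ratio and proxies ribosome load per transcript.
Comparing two conditions, three per-gene questions are asked — did mRNA
change, did footprints change, did TE change — and their joint answer places
the gene in a seven-way taxonomy whose most interesting corner is
*translational buffering*: TE shifts significantly while footprints do not,
i.e. the cell absorbed a transcriptional change without altering protein
synthesis.

## Count model and normalization

Samples are depth-normalized by median-of-ratios size factors computed over
genes expressed in every library, rescaled to geometric mean 1. Tests operate
on normalized counts `y` under a quasi-negative-binomial variance model

    Var(y) = b * mu + alpha_g * mu^2 .

`alpha_g` is the per-gene biological overdispersion; `b` is a single
*technical* coefficient shared by all genes (Poisson shot noise at unit depth
corresponds to `b = 1`). Both come from the replicate structure: for each
gene the pooled within-group variance `t`, the df-weighted mean of group
means `m1` and of squared group means `m2` give a dimensionless response
`t/m2 ~ CV^2` regressed across genes on `m1/m2 ~ 1/mean`; the slope is `b`,
the intercept the dispersion trend. Per-gene moment estimates
`max(0, (t - b*m1)/m2)` are shrunk toward the trend with a prior weight of 20
residual degrees of freedom (configurable `prior_df`). With two replicates
per group the per-gene estimate carries 2–4 df, so the shrinkage is strong by
design; heterogeneous real dispersions will be over-shrunk toward the trend,
which trades per-gene adaptivity for stable error control.

Estimating `b` rather than pinning it to 1 has a deliberate consequence:
every statistic depends on the data only through exactly scale-equivariant
quantities, so multiplying any one sample's counts by a constant changes no
log2FC, p-value or category (numerically ~1e-12). A fixed `b = 1` cannot
have this property because the Poisson term `1/mu` is not scale-free.

## Model fitting and tests

Per-gene log-linear models are fitted by iteratively reweighted least
squares, vectorized across genes (all genes share the design matrix):
working weights `mu/(b + alpha*mu)`, at most 100 iterations, convergence at
1e-8 on the coefficient change; non-converged genes are flagged and excluded
from multiple-testing adjustment. For the per-assay shift the design is
intercept + condition (two groups); for the TE shift it is the full
2x2 factorial intercept + assay + condition + assay x condition, whose
interaction coefficient equals log2FC(ribo) − log2FC(rna) — the TE fold
change. Both designs are saturated, so fitted means equal group means and the
point-estimate identity log2FC(TE) = log2FC(ribo) − log2FC(rna) holds to
numerical precision. Wald z-tests give p-values; Benjamini–Hochberg adjusts
them over tested, converged genes. Wald rather than likelihood-ratio keeps
one fit per gene; with moment-based dispersions a likelihood ratio would not
be better calibrated.

All-zero genes are reported untested. Genes with an all-zero treatment group
have an unbounded MLE; they surface as non-converged rather than producing
spurious infinite fold changes (after the background filter such genes cannot
occur, since every background gene has a positive count in every library).

## Classification

Significance means |log2FC| > 1 AND FDR < 0.01, strict inequalities, applied
uniformly to all three contrasts (defaults; both thresholds configurable).
The decision tree: a significant TE shift splits on whether footprints moved
significantly in the same direction (translationally induced/repressed) or
not (the two buffering classes, annotated with the mRNA direction); without
a TE shift, concordant significant shifts in both assays give the up/down
TE-constant classes; everything else — including a significant mRNA shift
alone — is unregulated. The classes partition the background: buffering +
translation-driven counts equal the TE-significant total, and all seven sum
to the background size. Genes with missing statistics are reported
separately as unclassifiable instead of being silently dropped.

Per-condition TE is (mean normalized footprints + 0.5) / (mean normalized
mRNA + 0.5); the pseudocount (configurable) keeps TE finite at zero cells.
Genes with TE > 3 or TE < 0.33 are flagged as extreme. Cross-assay agreement
is the Pearson correlation of log2 mean normalized counts, mRNA vs
footprints.

## Enrichment

Each (category, gene list) pair is tabulated as a 2x2 table inside the
background universe — lists are intersected with the background first, since
the background is the universe of the classification — and tested one-sided
for enrichment via the hypergeometric upper tail P(overlap >= a). The odds
ratio uses a 0.5 continuity correction only when a cell is zero (annotated).
Percent-intersect is the overlap over the list's background-restricted size.
BH adjustment runs across all testable rows of a run. Gene identifiers match
as exact strings (optional upper-casing); cross-identifier mapping is out of
scope.

## Artifact trimming

Template-switching library preparation prepends non-templated homopolymer
runs (poly-C, poly-T) to the 5' end of reads. `trim_artifacts` strips
successive maximal homopolymer runs of the artifact bases from the 5' end
(optionally 3' or both), each of length >= 3 by default, until the terminal
run no longer qualifies; this makes trimming idempotent even when runs of
the two bases stack. Reads shorter than 20 nt afterwards are discarded;
reads with non-ACGTN characters pass through untrimmed with a warning. A
read whose *biological* sequence itself begins with an artifact-like run is
intrinsically ambiguous — no trimmer can place the boundary — and the
simulator's ground-truth annotations let exactly that class be counted
rather than guessed.

## Synthetic data

The generator emulates a differentiation time course: conditions NPC, ED,
Neuron; two assays; two replicates each (twelve libraries). Per gene it
draws a baseline mean log-uniform over roughly 3–3000 counts, a baseline
log2 TE from Normal(0, 1) (so TE varies across genes and extreme-TE flags
occur), and negative-binomial counts with Var = mu + alpha*mu^2, default
alpha 0.05 — conventional values for bulk libraries, as the underlying
study does not report its dispersions or depth spread. Planted categories
are allocated by largest remainder, so realized class counts are exact, then
shuffled; effects of |log2FC| = 2 appear only in the last condition, with
the sign pattern of each class (e.g. buffering: mRNA ±2, footprints 0). ED
carries no effects, mirroring the observation that early differentiation
shows transcriptional but no TE changes. Default class proportions (63.4%
unregulated, 7.6% x2 TE-constant, 6.1% x2 buffering, 4.6% x2
translation-driven) mirror the fractions reported for differentiating
neurons.

What the generator does *not* emulate: mean-dependent dispersion trends,
sample-to-sample depth spread (available via `depth_factors` but defaulting
to 1), correlated genes, isoform structure, or sequence-level biology (no
alignment, UTRs, codons or uORFs). Passing recovery tests therefore show the
statistical machinery is correct under its own assumptions, not that a real
library's artifacts are handled; the trimming stage is exercised by its own
read-level simulator.

Gene lists for enrichment are drawn without replacement with a configurable
weight (default 10) on one category — weight 1 is a uniform background draw
whose downstream Fisher p is approximately uniform.

## Numerical choices and problem sizes

IRLS initialization is least squares on log(max(y, 0.5)); linear predictors
are clipped at ±30 to keep degenerate genes finite until they are flagged.
TSV outputs use a fixed `%.10g` float format, making repeated runs
byte-identical. The analysis scripts use 8000 genes; the test suite and the
acceptance script use 400–8000 genes and 5–20 simulation seeds per property,
sizes at which every Monte-Carlo bound tested (recovery >= 90% per planted
class at mean 500 and dispersion 0.01, null classification <= 2% at FDR
0.01, Poisson concentration) holds with margin while the whole suite runs in
well under a minute.

## Known limitations

- The dispersion prior is a single trend value; strongly mean-dependent or
  bimodal dispersion landscapes are over-shrunk.
- Wald tests on 2+2 replicates are approximate; p-values near the
  significance boundary should not be over-read, and the twofold effect
  threshold does most of the error control there.
- The technical variance coefficient `b` is shared across samples; libraries
  with very unequal depths mildly violate this pooling (per-sample weights
  would be exact but break the scale-invariance guarantee).
- Buffering classes key on TE significance plus footprint non-significance;
  the mRNA direction is annotated but not required, so a gene with a large
  TE shift and neither assay individually significant lands in a buffering
  class rather than a separate "TE-only" class.
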