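# Methods

This note documents the models and procedures `stromascope` implements,
the parameters that matter, and the choices made where the design was
genuinely open. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator (`synthetic_data`) emulates the statistical structure the
analysis assumes, not a real transcriptome. Counts for gene *g* in cell
*c* are negative binomial (gamma–Poisson) with mean

μ(g,c) = pᵍ · d꜀ · b(s꜀, g) · f(g,c)

where pᵍ is a per-gene baseline abundance (log-normal across genes,
`baseline_log_sd = 1.5`, normalized to sum to 1), d꜀ a per-cell
sequencing depth (log-normal, mean `sequencing_depth_mean = 5000` UMIs,
sd of log 0.3), b a multiplicative per-(sample, gene) batch effect
(log-normal with unit mean, `sample_effect_sd = 0.2`) and f a planted
fold change `2^signature_log_fold_change` applied to the marker genes of
the cell's major type, the signature genes of its stromal subtype, and
(optionally) an S or G2M program. Overdispersion is a shared NB
dispersion φ = 0.3 (var = μ + φμ²). Defaults: 5,000 cells, 2,000 genes,
8 samples (6 tumor / 2 normal), ages uniform in 35–85 shared by all
cells of a sample, a seven-type TME mixture dominated by T cells, five
EC and five fibroblast/myofibroblast subtypes at equal proportions, 40
signature genes per subtype, 25 marker genes per major type, 5% of genes
mitochondrial. Depth, batch sd, dispersion and fold changes are chosen
as typical of droplet scRNA-seq data; all are config fields.

Major type and stromal subtype are drawn independently for stromal
cells, so a cell labeled `Fibroblast` may carry the `C7_MYH11`
(myofibroblast) program: marker genes drive the major-type stage and
signature genes the subtype stage, and the two planted blocks are
disjoint, so the mild semantic overlap has no effect on either test.

Deliberately **not** modeled: gene–gene correlation beyond the planted
blocks, doublets, ambient RNA, zero inflation beyond NB sampling, and
library-construction biases. Passing tests therefore show the pipeline
recovers planted structure under the stated noise model — not that it is
robust to everything real data do.

## QC and transforms

Filters use strict inequalities: >200 and <6,000 detected genes, mito
fraction <25%, and >400 UMIs (UMI platforms only). Log-normalization is
natural-log `log1p` at scale 10,000 — the base is a convention choice;
the per-cell identity Σ(eᵛ − 1) = 10⁴ is asserted in tests. Full-length
data are rescaled per cell to TPM (column sum 10⁶; a no-op for true TPM,
the conversion for FPKM) then transformed `log2(TPM/10 + 1)`.

Cell-cycle scores are set-mean minus control-mean, with controls drawn
per program gene (100 with replacement, seeded) from the same
average-expression bin (25 rank-based bins), so a program scores against
transcriptionally comparable genes.

HVG ranking follows the VST recipe: loess trend (span 0.3) of
log10 variance on log10 mean over nonzero-variance genes, per-gene
standardization by the trend-predicted sd, clipping at √n_cells, and
ranking by the variance of the clipped values. Ties rank stably in gene
order. Scaling regresses each selected gene on an intercept, numeric
covariates (mito fraction, UMI count, S and G2M scores) and sample
indicator columns via minimum-norm least squares (collinearity is
therefore harmless), then centers, scales to unit variance and clips at
±10; constant genes map to zero rows. Regression is applied to the
selected HVGs only, which is all that clustering consumes. For
full-length data the covariates are mito fraction, sample identity and
cell-cycle scores (no UMI count, and detected-gene count is not
included).

## Clustering and annotation

PCA is centered, via full SVD, with a deterministic sign convention
(largest-magnitude loading positive). The elbow rule picks the smallest
dimensionality where the drop between consecutive explained-variance
ratios falls below `drop_tol = 0.001`, clamped to [10, 50], with the
upper clamp when the spectrum never flattens. Clustering is a Euclidean
kNN graph (k = 20) with Leiden modularity communities at resolution 0.8,
seeded; algorithm, k and resolution are unspecified by the analysis this
reproduces and are set to the de-facto single-cell standard, exposed in
config. Cluster annotation computes each marker set's mean expression
per cluster, z-scores it across clusters per set (so high-expression
sets cannot dominate), and assigns the argmax; exact ties go to the
lexicographically first type name with a warning. "Tumor cells" for
pathway comparisons are cells annotated Epithelial in tumor-tissue
samples; no CNV-based malignancy calling is performed — a documented
limitation.

## Subtype models and rejection

A subtype "model" is a centroid over the union of all signature genes:
the per-gene mean of labeled reference cells, or a binary indicator
centroid (1 on the subtype's own signature genes) when reference
expression is unavailable — both paths are implemented because either
reading of "a model built from subtype-specific genes" is defensible.
Similarity is Pearson correlation over the union (Spearman available),
which is exactly invariant to per-cell affine transforms of expression.
Significance is a per-model gene-permutation test: the cell's values
over the union are permuted (one seeded permutation set shared across
cells keeps the null fully vectorized), p = (1 + #{null ≥ obs}) /
(n_perm + 1), n_perm = 1000 by default. A cell is `unknown` when every
model's p exceeds α = 0.05 (and rejection is enabled). With K models the
expected null unknown rate is ≈ (1−α)ᴷ ≈ 0.77 for K = 5 — the reject-all
rule is deliberately not multiplicity-corrected, matching its
"not significantly similar to any model" reading. EC classification is
forced (no unknown); fibroblast classification rejects — the analysis
being reproduced reports no unknown ECs but explicitly allows unknown
fibroblast subtypes. Cells with zero variance over the union have
undefined correlation and are `unknown` with a warning.

## Composition conventions

Fractions are within-row; EC subtype fractions are over all classified
ECs, fibroblast "common-5" fractions over cells assigned to the five
common subtypes only (unknown and tissue-specific excluded via
`include_types`). Age classes: young <60, old ≥60, unknown when age is
missing (excluded from age comparisons). The shipped reference count
tables are transcribed verbatim, including one dataset row whose
declared totals duplicate another dataset's and disagree with its own
per-type counts; `consistency_check` reports the mismatch and does not
correct it (15 of 17 dataset/tissue columns are consistent). No
inferential statistics are attached to fraction differences —
descriptive deltas only.

## ssGSEA

Implemented from scratch in the "2.0" convention: genes ranked by
expression descending, score = Σ over ranked positions of (weighted
in-set ECDF − unweighted out-of-set ECDF), in-set weights =
(rank-normalized position)^α with α = 0.25, and per-set division by the
max−min of scores across the cells of a run. Rank weights (positions,
not raw values) give exact invariance under strictly monotone transforms
of expression and robustness to sparse zeros; raw |value|^α weighting is
available behind a flag. Ties — ubiquitous among zeros — break
deterministically by lexicographic gene name (or a seeded shuffle),
choosing reproducibility over fidelity to any particular
implementation's arbitrary internal order. The implementation is checked
exactly (|Δ| < 1e-9 on 1,000 random toys) against a loop-based oracle
written directly from the walk definition, and against an established
independent ssGSEA implementation on tie-free toys.

## Problem sizes and numerics

The test suite and acceptance script run simulations at 200–5,000 cells
and 900–1,500 genes — sizes at which every planted effect is detectable
with comfortable Monte-Carlo margins while the whole suite stays fast.
Statistical assertions use fixed seeds and tolerate sampling noise via
binomial/Monte-Carlo standard-error bands computed in the test, never by
loosened ad-hoc thresholds. Degenerate inputs (all-zero cells, constant
genes, zero score ranges, collinear designs, empty groups) follow the
conventions stated above: error when silently continuing would corrupt a
downstream stage, warn-and-handle when a well-defined value exists.

## Known limitations

- Gene identifiers match by exact string only; no alias resolution.
- The synthetic generator's independence assumptions make clustering
  easier than on real data; accuracy numbers on synthetic data are upper
  bounds, not forecasts.
- No batch integration across datasets: the design classifies each
  dataset against fixed reference models precisely to avoid pooling.
- No survival analysis, doublet detection, ambient-RNA correction or
  CNV-based malignancy inference.
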