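# Methods

This note documents the models and procedures implemented in
`maturatlas`, the parameter choices that matter, what the synthetic data
do and do not emulate, and the numerical decisions a user may want to
audit. Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data model and preprocessing

The in-memory container is an `AnnData`: integer UMI counts in `.X`
(cells × genes, sparse), per-cell metadata in `.obs` (`sample_id`, an
ordered categorical `age`, `sex`, `genotype`, `cell_type`) and per-gene
category flags in `.var` (mitochondrial, ribosomal, immediate-early,
apoptotic, red-blood-cell, Y-linked, X-inactivation). On disk a dataset
is a 10x-style Matrix Market triple plus a `cells.tsv` metadata table;
round-tripping is exact, including categorical age order.

**QC.** A cell is retained only if every rule holds: 400 ≤ UMIs ≤
100,000; ≥ 250 detected genes; top gene ≤ 20% of its counts;
mitochondrial and ribosomal fractions ≤ 10%; immediate-early, apoptotic
and red-blood-cell fractions ≤ 1%. The report records each cell's
metrics and the first rule it failed, and filtering is idempotent. The
UMI window is read as *retain* cells within the bounds — the natural
reading for a quality filter. Note the gene-detection floor is an
absolute count: synthetic panels much smaller than ~500 genes cannot
pass it, which is a property of the thresholds, not a bug.

**Normalization.** `x = ln(1 + c / total × 10⁴)` per cell. A published
variance-stabilizing transform could be substituted, but log-
normalization is fully specifiable, parameter-free and is what the
module-score and pseudotime stages assume. Zero-total cells are an
error, named.

**Highly variable genes.** Genes are ranked by dispersion
(variance/mean of log-normalized values) standardized within 20
equal-frequency bins of mean expression; ties break by gene id so the
ranking is deterministic. The bin count adapts downward so each bin
keeps roughly ten genes — standardizing within one- or two-gene bins is
meaningless (this matters for small simulated panels).

**PCA.** Centred, unit-variance-scaled HVG expression; randomized SVD
seeded, so results are reproducible. The component count used downstream
is the smallest *m* whose cumulative explained-variance fraction reaches
20%, capped at 100. With noisy high-dimensional data the cap is often
reached; distances then carry a noise floor (see §7).

**Module scores.** Mean expression of a gene set minus mean expression
of control genes drawn (seeded) from each set gene's expression-mean bin
(24 equal-frequency bins, 100 controls per set gene, pooled unique).
Never-expressed genes are excluded from the binning universe, making the
score invariant to padding the matrix with silent genes. Scores averaged
within ages can be z-scored across ages (population SD; a zero-SD series
maps to zeros by convention).

## 2. Maturation distance and trajectory classes

Per cell type: embed all ages jointly (§1), compute per-age centroids in
the leading *m* components, and take the Manhattan distance of each age's
centroid to the adult centroid. Ages with fewer than 10 cells are
dropped (configurable), never imputed. The raw series is monotonized by
a running minimum — transient excursions away from the adult state (for
example a wave of axon-guidance expression) are deliberately flattened
so the series reads as "how adult-like".

Classification operates on the monotonized series: order the inter-age
decreases largest first and find the smallest count *k* whose sum
reaches 90% of the total decline; *k* ≤ 2 → stepwise (class 3), *k* = 3
→ intermediate (class 2), *k* ≥ 4 → gradual (class 1). A series with no
decline has no class. Classes are computed after monotonization because
the classified object should be the same curve that is reported.

The nearest-neighbour maturity of an age is the fraction of adult cells
among the k = 50 Euclidean nearest neighbours (self excluded) of that
age's cells, pooled over cells, in the same embedding. Manhattan is used
for centroid distances and Euclidean for neighbour graphs, matching the
conventions of each analysis.

Trajectory sets are compared by a two-way fixed-effects ANOVA of
distance on age and cell-type group, with cell types as replicates; the
group main-effect p-value is reported.

## 3. Group contrasts

For one cell type and a two-group sample design, all pairwise Manhattan
distances between per-sample centroids are split into inter- and
intra-group sets. The effect size `mean(inter)/mean(intra)` is scale-free
and ≈ 1 under exchangeable labels; a two-sided Welch t-test compares the
two sets. Caveat, stated rather than hidden: pairwise distances are not
independent, and the sets are small (16 inter / 12 intra at 4 + 4
samples), so the t-test is approximate. We therefore verify calibration
empirically — 200 label-permuted null replicates give a median effect
size within [0.9, 1.1] and a type-I rate compatible with nominal — and
treat that, not the t distribution, as the warrant. BH adjustment across
cell types is applied for genotype contrasts; for sex contrasts raw
p-values with pseudobulk-DE corroboration are the intended workflow.

Pseudobulk DE sums raw counts per sample, removes mitochondrial,
ribosomal, Y-linked and X-inactivation genes (constitutively sex-biased
genes would otherwise dominate any sex contrast), and tests log₂-CPM
(prior count 0.5) per gene with a Welch t whose residual variance is
squeezed toward a lowess mean–variance trend with four pseudo-
observations of prior weight. A published NB shrinkage estimator could
replace this; the squeeze captures the same borrowing-of-strength idea
with fully stated steps, and its FDR behaviour is verified by
simulation. Significance is BH-adjusted p < 0.05.

## 4. Developmental DE, trends and summaries

`devdeg_test` applies a one-way moderated F-test of the age factor to
per-sample log₂-CPM pseudobulk, with the same variance squeeze
(denominator df increased by the prior df). Because the design is a
single factor, per-observation precision weights reduce to gene-level
variance moderation, which is what the squeeze provides. Ages with one
sample are excluded with a warning (a stage with only two samples, as at
the earliest embryonic stage of a typical design, is retained). devDEGs
are genes at BH FDR < 0.05.

Trends are fitted on the age-rank axis (0…7) — embryonic and postnatal
stages share no common day scale, and the stages function as ordered
categories. Five or more ages: cubic smoothing spline with the penalty
chosen by generalized cross-validation; exactly four: cubic least
squares; fewer: linear, with a warning. Trend matrices are min–max
normalized per gene (constant trends map to 0.5) and clustered with
Ward linkage on Euclidean distance; the cluster count is a parameter
(default 12) since no single value is canonical.

Sharing classes use strict inequalities: detected in > 70% of cell types
→ shared, < 20% → cell-type-specific, otherwise intermediate; the
boundaries themselves are intermediate. The refinement score of a gene
set is (significant gene × cell-type changes between the two refinement
stages) / (combinations with nonzero pseudobulk expression at ≥ 1 age),
with the two-stage contrast computed as a dedicated pseudobulk test —
not read off the all-age fit — and pseudobulk (not per-cell) expression
defining the denominator. Eigentrends are the first right singular
vector of the gene-centred trend matrix, sign-oriented to correlate
positively with the mean member trend; gene-wise constant offsets cannot
affect them. Gene sets enter eigentrend summaries only if their median
devDEG overlap across cell types is ≥ 40.

## 5. Label transfer

The reference model is a 150-component PCA over 2,000 HVGs of the
labelled reference with a k = 30 nearest-neighbour index. Query cells
are projected through the stored centring/scaling/rotation and receive
distance-weighted vote fractions over labels (an exact-distance match
takes the whole vote); scores are non-negative and sum to one. The
acceptance rule: take the top label if its score *exceeds* 0.8 (strict),
else if it exceeds 0.5 and is at least twice (≥) the second-best.
Unassigned cells are excluded from all downstream per-cell-type
statistics. Iterative age mapping labels the oldest pre-adult stage
against the adult data, then each younger stage against the union of all
older labelled stages, reporting per-age assignment rates and mean
score matrices with identity ratios ((diagonal − best off-diagonal) /
diagonal).

This scorer is a deliberate methodological substitution for anchor-based
canonical-correlation transfer: the acceptance thresholds act only on
score vectors, and a kNN soft vote keeps the procedure fully specified
and dependency-light. Equivalence of the scores themselves is not
claimed — only fidelity of the threshold rule and empirical label
recovery (≥ 95% on synthetic data with default markers).

## 6. Pseudotime and delay

Per cell type, control cells are embedded (2,000 HVGs, top 20 PCs) and a
principal curve is fitted: initialize the parameter with the first
component, then alternate (i) averaging cells within 50 quantile bins of
the parameter (a regressogram smoother) to get control points and (ii)
re-projecting all cells onto the polyline through those points.
Convergence is declared when the mean squared projection distance stops
improving (relative change < 1e-4) or projections stop moving; the
binned smoother reaches a fixed point in a handful of iterations,
whereas a raw displacement criterion oscillates with re-binning and
never triggers. The converged control points are polished once with a
GCV smoothing spline before arc lengths are finalized. Pseudotime is arc
length, oriented so adult cells exceed the earliest-age cells, and
normalized to [0, 1] by the training range — a common scale is required
because the delay test averages pseudotime across cell types.
Projection of held-out cells reuses the stored transform and curve;
training cells re-project to their stored values to machine precision.
Pseudotime is stable under duplicating every cell up to bin-boundary
effects (a few percent), and for collinear data it is monotone in the
position along the line.

**Delay testing.** Cells are averaged within (age, genotype, cell
type); per age, a two-sided t-test compares mutant and control cell-type
means (≥ 5 cell types per genotype required, else the age is skipped).
The delay estimate is the integer stage shift d minimizing the mean
squared difference between the mutant per-age profile and the control
profile shifted d stages earlier, excluding the final age (a transient
delay has converged there by construction).

**Study design note.** Curves are fitted on *reference* control samples
and both genotypes are then projected as held-out data. Projecting
training cells alongside held-out mutants would be biased at the curve
endpoints: the curve overfits its own training cells there, so held-out
cells of an identical distribution project systematically differently.
The reference/littermate split removes this asymmetry, and matches how
such comparisons are designed in practice (a wild-type reference
dataset, with mutant and littermate-control cells both projected).

**Core maturation genes.** A seeded, balanced subsample of ten cells per
cell type at the youngest stage(s) (first two, pooled) and at the adult
stage; per-gene log₂ fold change of adult vs young on expm1-averaged
log-normalized expression; keep genes with log₂FC > 0.5 expressed in
≥ 30% of the sampled adult cells. The derived set is reproducible given
the seed. Module-score comparisons between genotypes compute the score
on the pooled matrix (shared control bins), average per cell type, and
t-test across cell types.

## 7. The synthetic-data generator

Counts are negative binomial with Var = μ + μ²/θ (θ → ∞ recovers
Poisson) and log-normal library sizes: `X ~ NB(μ_gc(t)·depth/E[depth],
θ)`. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| ages | E16…P65 (8 stages) | the atlas design being emulated |
| samples per sex per age | 2 | the atlas design (4 per group in contrast studies, matching the pooled-control designs used for such tests) |
| library size | log-normal, E ≈ 5,300 UMIs | thousands of UMIs per nucleus, the scale of droplet snRNA-seq |
| θ (inverse overdispersion) | 2.0 | realistic UMI overdispersion |
| gene panel | 2,000 genes | emulates the HVG subspace the pipeline operates in |
| trend gene fraction | 0.5 | developmentally regulated genes are a large fraction of HVGs in a developing brain atlas (thousands of shared devDEGs against a 2,000-gene panel) |
| trend amplitude | 2.0 (natural log) | strong but plausible developmental fold changes (~7×) |
| markers per cell type | 50, at 8× baseline | cell types differ in dozens of well-expressed program genes; far fewer makes identity unlearnable in a 150-PC space |
| gene category fractions | ≤ 1% of genes each, ≤ 3% of counts | post-QC nuclei have small mitochondrial/ribosomal shares |

Age trends are defined on the age-rank axis and mean-centred in log
space (so the trend assignment does not disturb library-size
calibration). Gradual genes follow the cell type's *maturation clock*
p(t) ∈ [0, 1] — evenly increasing for planted class 1, concentrated in
three steps (class 2) or two steps (class 3), the concentrated steps
falling at the pre-weaning and pubertal transitions. Step and transient
genes use their own planted stage; transient peaks are restricted to
intermediate stages so they never mimic monotone genes. Trends are
planted only on detectably expressed genes (above the 30th abundance
percentile) — a trend on a never-observed gene is not recoverable ground
truth by any method. Y-linked genes are near-silent in females and
X-inactivation escapees female-biased, the reality that motivates the
DE exclusion rule; configured sex effects multiply chosen genes in
female cells of chosen cell types and ages. The mutant genotype's clock
lags by `delay_stages` at pre-adult stages and has converged at the
final stage — a *transient* delay.

What the generator does **not** emulate: doublets, ambient RNA, batch
chemistry, spliced/unspliced layers, cell-type abundance differences
(per-type cell counts are uniform and configurable), branching lineages,
or realistic gene–gene correlation beyond what shared clocks induce.
Passing tests therefore demonstrate that the statistics recover their
planted targets under the stated noise model — not robustness to those
artefacts.

**Noise floor.** Centroid distances between finite samples carry a
positive bias (every component contributes |noise|), which collapses to
0 only at the adult stage, where the distance is to itself. The
classification is therefore reliable when planted signal dominates the
floor — the regime the default parameters target, and the regime in
which real atlases resolve gradual from stepwise classes. Validation
confirms ≥ 90% class recovery at 300 cells per age.

## 8. Validation studies and sizes

All quantitative claims are computed by `maturatlas.studies`, shared by
the test suite and `scripts/acceptance.py`; replicate sub-seeds derive
from the caller's seed via `SeedSequence`. Problem sizes were chosen so
the whole validation runs in a few minutes on one CPU: 30 cell types ×
300 cells/age for class recovery; 200 null and 25 power replicates for
the contrast statistic (one cell type, two ages, 4 samples/sex, 50
cells/sample); 20 runs × 6 cell types for delay recovery; 50 null and 10
power simulations for devDEG calibration; 8 cell types × 1,500 genes for
core-gene recovery. Under the complete null the realised FDR equals the
probability of any discovery, which is the quantity the calibration
study reports.

## 9. Known limitations

- The distance t-test treats dependent pairwise distances as
  independent; calibration is empirical, not theoretical.
- The moderated-variance DE tests use a fixed prior df (4) rather than
  estimating it empirically per dataset.
- Trajectory classes inherit the centroid noise floor; with few cells
  per age the final inter-age step absorbs the floor and biases toward
  stepwise calls.
- The principal curve is unbranched by design; data with genuine
  branching need a lineage-inference method.
- The kNN label-transfer scores are not numerically comparable to
  anchor-based prediction scores, only rule-compatible.
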