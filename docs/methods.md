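# Methods

This note documents the models, estimators and design choices behind
`crosstalk`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, which
knobs matter, and what the synthetic validation does and does not show.

## 1. The ligand–receptor pair database

The unit of analysis is a curated (ligand, receptor) interaction record.
Gene symbols are upper-cased on load; duplicates are dropped with a
warning; a record whose ligand and receptor symbol coincide is rejected
(its co-expression would be a self-correlation of 1 by construction).
Relations are non-bijective: the per-ligand receptor group drives the
sum-over-receptors rule in the bulk correlation stage, while the
single-cell stage treats every (L, R) record independently. No alias or
orthology resolution is attempted — symbols must match the expression
matrices exactly, and unmatched pairs are skipped with a logged count.

The background combinatorics of a resource of n pairs is n(n−1)/2
unordered combinations (3,270,403 for n = 2,558), computed in exact
integer arithmetic. The *statistical* background, however, is drawn from
the ligand-set × receptor-set cross product minus the curated pairs and
same-symbol cells, sampled uniformly without replacement under a mandatory
seed. The two notions are deliberately separate: the first reproduces the
combinatorial count, the second is the well-defined null actually used for
comparison. The full cross product is never enumerated per-correlation;
a seeded subsample (default 1,000 in the pipeline, clamped to the number
of available non-interacting combinations) gives statistically
indistinguishable summaries at a fraction of the cost.

## 2. Differential expression: moderated t

Expression is transformed to log2(x + c) with pseudocount c = 1 (bulk
RNA-seq abundance estimates are non-negative and heavy-tailed; the
pseudocount is configurable). Per gene, ordinary least squares on the
two-group indicator design yields the contrast coefficient — exactly the
difference of group means in log2 units — the residual variance s² and
residual df d. The fold-change threshold is applied to this model
coefficient (not the raw mean ratio); with indicator coding and the log
transform the two agree up to the pseudocount.

The empirical-Bayes step assumes s² | σ² ~ scaled χ²_d and a scaled
inverse-χ² prior for σ² with df d₀ and scale s₀². The prior is estimated
by moment matching on e = log s² − ψ(d/2) + log(d/2): the excess of
Var(e) over ψ′(d/2) equals ψ′(d₀/2), inverted by bisection on the
trigamma function to relative tolerance 1e-8; a non-positive excess gives
d₀ = ∞ (complete shrinkage, all posterior variances equal to s₀²).
Moment estimation requires ≥ 10 genes; residual variances below 1e-24 are
treated as exact fits (floating-point dust) and dropped from the prior
fit. The moderated t uses the posterior variance
s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d₀ + d df. Forcing d₀ = 0 recovers the
ordinary t exactly; the implementation agrees with Bioconductor limma
(`lmFit` + `eBayes`) to 1e-6 on a shared fixture, and its raw-P type-I
error on simulated null cohorts is nominal (≈ 0.05 at α = 0.05).

Gene selection defaults to |log2FC| ≥ 1 and raw P ≤ 0.05, both inclusive;
an option switches the gate to the Benjamini–Hochberg adjusted P. Pair
regulation scenarios are the joint member directions: both_up, one_up,
both_down, one_down, plus `discordant` (one up, one down — a combination
the four classical scenarios do not cover, reported separately) and
`none`. The assignment is exhaustive and mutually exclusive over the 3×3
direction grid.

## 3. Pair correlation and distribution comparison

Spearman's ρ (midranks for ties) is computed between the ligand's
expression and the element-wise **linear-scale sum** of its cognate
receptors, per condition, requiring ≥ 3 samples; constant vectors yield a
missing value with a warning. Summation on the linear scale follows the
convention of adding transcript abundances before ranking; because
Spearman is invariant to monotone transforms, the choice of scale matters
only when the summation changes rank order (multiple receptors of
comparable magnitude). Random pairs get no summation — a non-cognate pair
has no defined receptor group.

Distributions of ρ are summarized by mean, sd (ddof = 1) and the
coefficient of variation sd/|mean| (reported as missing when the mean is
numerically zero), and compared by the two-sample Kolmogorov–Smirnov
statistic with the asymptotic P-value; exact small-sample P-values are out
of scope, and for the hundreds-to-thousands of pairs involved the
asymptotic approximation is adequate.

## 4. Correlation-shift areas and the noise band

With thresholds (−0.25, 0.25) for "uncorrelated" and ±0.5 for
"correlated", a pair's (ρ_normal, ρ_cancer) point falls in area I
(uncorrelated → > 0.5), II (< −0.5 → uncorrelated) or III
(> 0.5 → uncorrelated), else `none`. All inequalities are strict, so
boundary values are conservatively unclassified; the three areas are
disjoint by construction and the classifier is brute-force verified to
partition a 0.01 lattice of [−1, 1]². All four cut points are
configurable.

The ±0.25 band is a measurement-noise calibration, not a biological
constant: `estimate_noise_band` draws two random same-size subsets of one
condition's samples (independently, so they may overlap — e.g. two groups
of 65 from 112 samples necessarily share members), recomputes all pair
correlations in each, and returns the 95th percentile of |Δρ| pooled over
pairs and repetitions. On simulated homogeneous cohorts of 112 samples
with groups of 65 this yields ≈ 0.19, consistent with the ±0.25 default;
the band shrinks as the group size grows.

Recurrence ranking across cohorts sorts pairs within each area by
(number of cohorts in the area, mean |ρ_cancer − ρ_normal|, pair name) —
the tie-breaks make the ordering deterministic; top 15 by default.

## 5. Infiltration stratification

Cancer samples are split at the q = 0.25 quantiles of an admixture
fraction (lymphocyte, monocyte, neutrophil or stromal): high group
≥ the (1−q) quantile, low group ≤ the q quantile, midpoint interpolation,
ties included on both boundaries (groups can therefore exceed ⌈qn⌉; an
all-identical fraction column degenerates to both groups containing all
samples, with a warning). Pair correlations are recomputed within each
group — the only reading under which "the correlation distributions of
two groups" are comparable objects — and compared by a 99-point Q-Q match
and the K-S test. Under the no-association null the comparison is clean
(P > 0.01 in ≈ 98% of simulated replicate cohorts); a planted coupling of
one pair's correlation to a fraction is detected as a group difference
well above the noise band.

## 6. Single-cell communication network

Working scale: the caller decides (raw counts, CPM, log-normalized — the
rule is scale-parameterized and all calls are invariant under global
rescaling). For each gene a threshold x̄ + k·σ is formed and a cell type
is called "high" when its mean expression exceeds it; k defaults to 3 and
is tunable. A gene with zero threshold-scope σ is never called.

**Scope of x̄ and σ — an important subtlety.** Computing the moments over
the T per-type means themselves makes the rule vacuous: by Samuelson's
inequality no value among T can exceed the mean by more than
(T−1)/√T sds (≈ 2.27 for T = 7 < 3), so at k = 3 this variant never fires
on any input — it is retained as `stat_scope="type-means"` for
demonstration only. Pooling all cells (`stat_scope="pooled"`) has a
subtler version of the same problem: a type holding a fraction p of the
cells can never exceed the pooled mean by more than √((1−p)/p) pooled
sds — √6 ≈ 2.45 for seven equal-sized types — because the between-type
spread that makes a type an outlier also inflates the pooled σ. The
pooled rule therefore only fires when type abundances are very unbalanced
(p < 1/10 at k = 3), which real dissociated-tumor datasets happen to be.
The default, `stat_scope="rest"`, computes x̄ and σ from the cells
*outside* the focal type: it asks exactly the intended question — is this
type an outlier relative to the rest of the tissue? — is immune to both
bounds, recovers planted signal with precision = recall = 1 on balanced
synthetic data, and calls nothing under the null.

Edges: for every pair record and every ordered type pair with the ligand
high in the sender and the receptor high in the receiver, one directed
edge is emitted; autocrine (self) edges are allowed, and counting is
ordered (sender → receiver). Exclusiveness of gene g in type t is the
type's mean divided by the unweighted mean of the per-type means (1 for a
uniform gene, T for a one-type gene). An edge's score is the geometric
mean of sender-ligand and receiver-receptor exclusiveness — symmetric,
and zero when either side is non-exclusive; the combination rule is a
package choice, as is the lexicographic tie-break. The top ⌈fraction·N⌉
edges (default 2%) are reported, and the graph is exportable as GraphML.

## 7. The synthetic-data generator

The generator emulates the structure of the real study inputs, not their
biology:

* **Bulk cohorts** — independent genes except where a pair correlation is
  planted through a Gaussian copula: the latent bivariate-normal
  correlation is r = 2 sin(πρ_s/6), the exact inverse of the normal-score
  Spearman map, so continuous marginals inherit the target ρ_s
  (calibration error of the mean realized Spearman is < 0.01 at n = 300).
  Targets are capped at |ρ| ≤ 0.95 and pairs may not share genes (joint
  planting across overlapping pairs is infeasible in general and
  rejected). Marginals: log-normal with σ_log = 0.5 (CV ≈ 53%, typical of
  moderately expressed genes across patients; the mean is exact by the
  −σ²/2 offset) or negative binomial with dispersion 10 on counts.
  Differential expression multiplies the cancer mean by 2^log2FC.
* **Infiltration** — Dirichlet fractions with a dominant tumor-purity
  component (mean fractions ≈ 12/8/4/16% for
  lymphocyte/monocyte/neutrophil/stromal), so the four fractions are in
  [0, 1] and sum below 1. The optional association mode regenerates one
  pair's genes with different planted correlations above/below the median
  fraction.
* **Single cells** — negative-binomial counts per (type, gene), the
  standard overdispersed model for scRNA-seq counts, baseline mean 1 and
  dispersion 10; a planted edge multiplies the ligand mean in the sender
  and the receptor mean in the receiver by an elevation factor (default
  20).

Seeds are mandatory everywhere; a spec without a seed does not construct,
and identical seeds reproduce matrices bit-for-bit.

Not emulated: library-size variation, dropout/ambient RNA, doublets,
batch effects, gene–gene correlation structure beyond planted pairs,
tumor purity effects on bulk expression, and non-independence between
expression and infiltration beyond the explicit association mode.
Passing the recovery tests therefore demonstrates correctness of the
estimators and decision rules under their stated models — not robustness
to the full messiness of real tumor data.

## 8. Validation problem sizes

The shipped validation suite uses: 2,000-gene × (30+30)-sample null
cohorts (50 replicates) for moderated-t calibration; n = 300 per
condition and 50–100 seeds for copula calibration and shift-area
recovery; 60-pair cohorts at n = 100 per condition for the degradation
and dispersion contrasts; 100 replicate 60-sample cohorts for the
infiltration null; and 7 types × 200 cells with 5 planted edges at
elevation 20 (50–100 seeds) for network recovery. These sizes put the
Monte-Carlo error comfortably below every margin being asserted while the
whole suite runs in well under a minute per stage.

## 9. Known limitations

* Bulk co-expression across patients is a proxy; it cannot distinguish
  autocrine from paracrine signaling, nor co-expression driven by shared
  cell-composition changes from genuine communication.
* The pipeline performs no per-pair significance testing or
  multiple-testing control over pairs; the areas I–III are descriptive
  classifications relative to a calibrated noise band.
* The sum-over-receptors rule covers the one-ligand–many-receptors
  direction only; many-ligands–one-receptor relations remain independent
  pair records.
* K-S P-values are asymptotic; with very few pairs they are approximate.
* The single-cell stage takes cell-type annotations as given and attaches
  no statistical significance to edges (no label-permutation test).
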