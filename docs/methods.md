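# Methods

`ratiosurv` implements a network-guided discovery pipeline for combinatorial
gene-expression ratio predictors of breast-cancer survival: a weighted gene
coexpression network nominates two anticorrelated module communities, per-gene
survival screens select candidates from each side, and an exhaustive
equal-weight ratio screen ranks every numerator/denominator combination by
fixed-horizon survival ROC AUC, with bootstrap machinery for comparing
predictor rounds.

## Data model and preprocessing

Expression data are linear-scale, non-negative gene × sample abundances
(FPKM-like RNA-seq quantities or array intensities). The default sample-wise
normalization rescales every sample so its total abundance equals the
cohort-median column total; this keeps values non-negative, which the ratio
scorer requires. A `median-centering-on-log` variant and gene-wise
`unit-median` / `z-on-log` options are available. The two normalization
methods are individually idempotent; their composition is not (gene scaling
perturbs column totals), so only per-method idempotence is guaranteed.

Sample QC removes outliers by standardized network connectivity: each
sample's connectivity is the sum of its Pearson correlations to all other
samples; samples below `z_cut = −2.5` standard deviations (a common
network-QC convention) are excluded. Duplicated gene symbols are collapsed to
the row with the highest mean abundance; genes with more than 20% missing
values are dropped, the remainder median-imputed. Batch correction is out of
scope — inputs are assumed pre-corrected, and a warning is emitted if a
`batch` covariate is present.

## Coexpression network

Pairwise gene similarity is the biweight midcorrelation (bicor), a
median/MAD-based robust correlation with Tukey weights
w = (1 − u²)²·1{|u| < 1}, u = (x − med)/(9·MAD). Because the weights depend
only on each vector's own median and MAD, the full bicor matrix is an inner
product of per-gene transformed vectors, which keeps the 10³–10⁴-gene case
fast. A vector with zero MAD falls back to Pearson behaviour (logged); binary
traits are correlated with Pearson outright, since bicor degenerates on
two-valued data.

The adjacency is signed by default, a = ((1 + r)/2)^β with β = 12. A signed
network is essential here: the pipeline's premise is a pair of mutually
anticorrelated module communities (low-in-TNBC vs high-in-TNBC), and an
unsigned network would fuse them into one module — the package's tests
demonstrate exactly this contrast. A scale-free-fit helper
(`pick_soft_threshold`) selects the smallest β whose connectivity
distribution fits a power law with R² ≥ 0.80 when β is to be chosen from
data.

Genes are clustered by average linkage on the topological overlap
dissimilarity 1 − TOM, where
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij). The tree is cut
statically at `cut_height = 0.99` of the maximum merge height. This
particular rule was chosen because pure-noise genes merge at dissimilarities
within a fraction of a percent of the maximum, so they fall above the cut and
stay unassigned, while factor-driven blocks merge far below it; a
fixed absolute cut would need retuning with β. Clusters below
`min_module_size = 30` are unassigned; modules whose eigengenes correlate
above `merge_corr = 0.75` are merged iteratively; surviving modules are
renumbered M1, M2, … by descending size. A dynamic hybrid tree cut is
deliberately not implemented — the static cut is reproducible and
oracle-testable.

Each module is summarized by its eigengene: the first right-singular vector
of the module's standardized log2 expression (unit norm over samples),
sign-oriented so the mean member correlation is positive;
`variance_explained` is the leading singular value's share. Module membership
kME is the Pearson correlation of a gene's log2 profile with each eigengene;
genes with own-module kME ≥ 0.6 are hubs (0.70 is used for enrichment-style
hub sets). Module–trait association uses bicor with the Student t
approximation p = 2·P(T_{n−2} > |r|√(n−2)/√(1−r²)), plus Kruskal-Wallis
across the four subtypes and a Wilcoxon rank-sum test of TNBC versus pooled
non-TNBC per module. Covariates (age, race, …) can be regressed out per gene
by OLS on the log2 scale before recomputing eigengenes.

## Differential expression

TNBC is compared with each receptor-positive subtype by an unpaired
two-tailed t-test on log2(x + 1); the Welch (unequal-variance) form is the
default because nothing guarantees equal group variances, with the pooled
variant selectable. Benjamini-Hochberg FDR is computed across all genes per
comparison (via `statsmodels`). Two distinct thresholds coexist by design:
DEG *counting* uses FDR < 0.05 with |log2 fold change| > 0.58 (a 50% change,
both strict), while the three-way *consistency filter* keeps genes with raw
p < 1e-4 and an identical direction of change in all three pairwise
comparisons. Module-aware DEG ranking sorts by ascending FDR with ties broken
by descending |log2 difference|, then gene id.

## Survival screens

The Kaplan-Meier product-limit estimator and the Mantel-Cox log-rank test are
implemented in-package because the screens need the Mantel-Haenszel hazard
ratio HR = (O_high/E_high)/(O_low/E_low) with its log-normal 95% CI
exp(ln HR ± 1.96·√(1/E_h + 1/E_l)), and an explicit tie convention — events
precede censorings at tied times — neither of which the usual survival
libraries expose directly; `lifelines` serves as the independent
cross-check in the test suite. Cox regression is deliberately not used: the
dichotomized log-rank/HR framing is the screen's contract. Expression units
(eigengenes or single genes on the log2 scale) are split at the median by
default (deterministic and outcome-blind; ties at the median go to the low
group), with tertile-extremes and fixed-threshold variants available.
Direction codes record "+" when high expression accompanies high survival
(HR < 1) and "−" for the opposite; BH q across the screened units is
reported alongside raw p.

Nomination applies the published rules to the single-gene screen: a gene
enters a ratio panel when min(log-rank p, any alternate-platform override)
is strictly below 0.015, its array probe is available, and it is not an
excluded known driver (ESR1 by default — its dose effect reflects receptor
status itself). Platform overrides (e.g. OPRK1's array p = 5.6e-4) are
explicit configuration, not special cases.

## Ratio screening

A ratio candidate is an ordered pair of disjoint gene sets: numerator genes
from the good-prognosis (down-in-TNBC) module side, denominator genes from
the anticorrelated side, so a larger ratio predicts better survival. Within
each sample the equal-weight score is

    score_s = Σ_{g∈N} x̃_gs / Σ_{g∈D} x̃_gs ,

where x̃ is the abundance after gene-wise unit-median scaling — the scaling
is what makes the weights "equal": without it a single high-abundance gene
dominates the sums. Mean and geometric-mean combinations are selectable.
Samples with a zero denominator are floored at half the smallest positive
denominator value in the cohort and flagged, never dropped silently. The
score is invariant to per-sample positive rescaling and maps to its
reciprocal under numerator/denominator swap.

Enumeration produces every k:k subset pair for k ∈ {1, 2, 3} plus the full
panel pair (when distinct), in deterministic lexicographic order. Outcomes
at a horizon t follow fixed-horizon ROC practice: an event by t is positive,
follow-up through t is negative regardless of later events, and censoring
before t excludes the sample, since its status at t is unknown. The AUC is
computed by the Mann-Whitney rank formula for
P(score_survivor > score_case) + ½·P(tie), identical to trapezoidal ROC
integration (property-tested against it). Default horizons are 15 months,
18 months, 3 years, 5 years, and 7.5 years (TNBC) or 10 years (all-subtype).
Ranking uses the maximum AUC across usable horizons with mean AUC as
tie-break, since both maxima and averages are quoted when screens of this
kind are reported; mean-first ranking is a flag away. The screen is fully
vectorized (indicator-matrix products for scores, axis-wise ranking for
AUCs) and processed in 100,000-combination blocks so memory stays bounded
for large pools; rerunning with the same inputs reproduces the table
byte-for-byte. Cross-platform validation applies a *fixed* spec to a second
cohort under the same normalization with no re-selection.

Weighted (regression-fit) gene combinations are a non-goal: the equal-weight
rule is the design under study.

## ROC uncertainty and round comparison

AUC significance against the 0.5 null uses the Mann-Whitney normal
approximation with tie correction. The 95% CI is a stratified bootstrap
percentile interval (resampling cases and controls separately, B = 2000 by
default, seeded); classes smaller than 5 flag the CI unstable. Two paired
predictors are compared for improvement with a stratified paired bootstrap:
sd(ΔAUC) over B replicates gives z = (AUC₁ − AUC₂)/sd and one-sided
p = 1 − Φ(z); identical predictors return p = 1 with a degeneracy flag.
Whether published CIs of this kind are bootstrap or analytic is generally
unstated; the bootstrap percentile form was chosen as the assumption-light
default, DeLong variances are a documented alternative not implemented in
v1.

## Set-overlap enrichment

`hypergeom_overlap` computes the exact upper-tail hypergeometric
P(X ≥ k) with the sample odds ratio k(N−n−K+k)/((n−k)(K−k));
`batch_fisher` runs one-tailed Fisher exact tests across named sets with BH
correction. Only overrepresentation (upper tail) is tested. No ontology
database is bundled — callers supply their own gene sets.

## Synthetic cohorts

The generator draws log2-expression x_gs = μ_g + λ_g·f_{m(g),s} + ε_gs with
per-sample module factors f, then exponentiates to the linear scale.
Defaults: 1,000 genes, 493 samples in subtype proportions
226 LumA : 118 LumB : 57 HER2 : 92 TNBC, six modules covering 55% of genes
(the rest background noise), loadings λ ≈ 1 with ±20% jitter, noise
σ = 0.7 (within-module correlation λ²/(λ²+σ²) ≈ 0.67), baselines
μ ~ U(3, 8). The first two modules form the anticorrelated pair: their
factors are jointly normal with ρ = −0.8, and tumour subtype shifts them in
opposite directions along a severity continuum (LumA 0, LumB δ/6, HER2 δ/3,
TNBC δ, with δ = 1.5) — emulating the down-in-TNBC / up-in-TNBC module duo.
Subtype affects survival only through these factors, isolating the mechanism
the screen must detect.

Survival uses an exponential hazard h₀·exp(γ·z) with z the standardized log
planted-ratio score (planted numerator genes from the first module of the
pair, denominator genes from the second; γ < 0 so a larger ratio means
better survival), under uniform administrative censoring on a 10-year
window. A second, "binormal" label mode generates a single-horizon outcome
whose class-conditional score distributions are *exactly* the balanced
two-Gaussian mixture with unit sd and mean gap Δ: a reference binormal
sample is drawn and its component labels are transferred to the cohort by
matching score ranks, so the joint law of (score rank, outcome) is that of a
true binormal sample and the closed form AUC = Φ(Δ/√2) applies exactly.
This mode backs the oracle tests and the acceptance measurements
(Δ = 1 ⇒ AUC = 0.760).

What the generator does **not** emulate: platform-specific array noise,
batch structure, the six intrinsic TNBC subtypes, non-proportional hazards,
or informative censoring. Passing tests therefore show that the pipeline
recovers planted structure under its own assumptions — linear-Gaussian
factor expression and outcome linked to a single ratio score — not that it
would perform identically on real cohorts.

## Problem sizes and numerical choices

The packaged measurements use sizes chosen to make each property estimable
with comfortable margins: planted-ratio AUC is averaged over five
2,000-sample binormal cohorts (Monte-Carlo sd of the mean ≈ 0.005 against a
±0.02 check); top-1% recovery of the planted 3:3 spec among 8+8 pools
(3,985 combinations) is measured over 20 seeds at n = 300; network recovery
runs 1,000 genes × 300 samples; null calibration suites use 300–1,000
replicates per statistic with Kolmogorov-Smirnov uniformity checks at
α = 0.01. Decoy pool genes for the recovery task come from modules
unrelated to the planted pair, mirroring candidate lists that mix
survival-linked and unlinked genes.

Degenerate inputs are handled explicitly rather than silently: constant
genes get kME 0 with a flag, zero-variance t-tests report p = 1 flagged,
single-gene modules warn and use the standardized gene as eigengene,
correlation p-values are floored at the smallest positive double, and the
ratio scorer's zero-denominator floor is logged per sample.

## Known limitations

- The exact preprocessing recipe (batch correction, the array
  normalization mirrored by `total-scaling`) behind published cohorts of
  this design is not recoverable; the defaults are documented stand-ins.
- The published module count (22) and DEG totals are cohort-bound and not
  reproduced; likewise external-cohort AUC values.
- The full 1:1/2:2/3:3 enumeration over 24+34 pools exceeds 150,000
  combinations; any additional constraint that would reduce it to a
  particular published total is not inferable, so the package enumerates
  the literal rule and reports the count.
- No Cox modelling, no dynamic tree cut, no GO enrichment, no count-based
  (negative binomial) differential expression.
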