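# Methods

`plasmanet` implements the analysis chain used in discovery plasma
proteomics of neurodegeneration cohorts: proximity-extension-assay (NPX,
log2 relative abundance) matrices are quality-controlled, adjusted for
age and sex, decomposed into co-expression modules, and related to
clinical groups, gene sets, biomarker panels, and clinical or
neuropathological traits. Because cohort data of this kind are shared
only on request, the package ships a synthetic cohort generator that
reproduces the statistical structure the methods assume; every pipeline
stage is validated against the generator's planted ground truth.

## Quality control

**LOD masking.** An assay's limit of detection is its median log2 buffer
signal plus three buffer standard deviations (the buffer SD reflecting
historically recorded background variance and taken as input). Cells
strictly below the limit are coded missing; values equal to the limit are
kept.

**Protein filters.** QC-warned assays are dropped first. Among assays
sharing a UniProt accession exactly one is kept — lowest missing
fraction, then highest variance, then lexicographically smallest assay
id; the tie-break is our choice, since only the removal itself is
standard. Proteins with missing fraction strictly greater than 0.5 are
then removed (exactly 50% missing is retained).

**Sample outliers.** Per-sample connectivity is the sum of biweight
midcorrelations with every other sample over pairwise-complete proteins
(bicor for consistency with the network stage; Pearson available).
Samples with standardized connectivity Z < −3 are removed in a single
pass. The rule is one-sided because a decorrelated sample can only lose
connectivity, and single-pass because a well-behaved cohort produces one
removal event; iterating would re-standardize against a shrinking
reference.

**Covariate adjustment.** Each bootstrap replicate resamples samples with
replacement within case-status groups (stratification keeps the group
dummies estimable) and fits ordinary least squares
`protein ~ age + sex + group` per protein on its non-missing cells,
grouping proteins by missingness pattern so each replicate is a handful
of small linear solves. The element-wise median over 1,000 replicates of
the age and sex coefficients is multiplied by the raw (uncentered)
covariates and subtracted; group terms are estimated but never removed,
protecting case-related variance. Subtracting against raw covariates
shifts the matrix mean by a constant, which no downstream statistic sees.
With `resample=False, n_boot=1` the procedure reduces exactly to a single
OLS fit, which the tests use as the closed-form oracle. Replicates with a
singular design (e.g. a resample lacking one sex) are redrawn, with a
capped retry count.

## Co-expression network

The correlation is the Tukey biweight midcorrelation: with
u = (x − median)/(9·MAD), weights w = (1 − u²)²·1[|u| < 1]; a vector with
zero MAD falls back to mean-centering with unit weights. For matrices
with missing data, per-column medians/MADs are computed on observed
values and each pair's numerator and denominators are restricted to
jointly observed rows; the exact pairwise definition (per-pair medians)
is used for vector calls, and complete-data columns agree between the two
paths to machine precision.

Signed adjacency is a_ij = ((1 + c_ij)/2)^β with β = 7.5 — the soft
threshold is a fixed analysis setting of this pipeline family, not fitted
to scale-freeness, and non-integer powers are accepted as-is. Topological
overlap uses the mean-denominator variant,
TOM_ij = (l_ij + a_ij)/((k_i + k_j)/2 + 1 − a_ij), with the min
denominator available.

**Module detection.** Average-linkage clustering of 1 − TOM (scipy;
single-block, suitable for a few thousand features) followed by an
adaptive branch cut. A branch qualifies as a cluster when it (i) has at
least `min_module_size` members, (ii) has a compact core — the mean of
the lowest merge heights joining its first `min_module_size` members must
stay below a deep-split-dependent fraction of the height range — and
(iii) hangs below its attachment point by a minimum gap. The
`deep_split` level 0–4 maps to core-scatter limits 0.64–0.95 with gap
fractions shrinking correspondingly, the standard sensitivity grid. Two
departures from the textbook formulation, made after inspecting
average-linkage trees of realistic TOM matrices:

- the attachment height is carried down through *chain nodes* (merges
  that peel off sub-minimum side branches), because singleton chains near
  the top of the tree otherwise mask every well-separated cluster below
  them;
- the minimum gap is referenced to the dendrogram cut height (0.99 of the
  top height) rather than to the truncated height range, giving the gap
  an absolute scale: in an unstructured (pure-noise) tree all branches
  attach within a sliver of each other and can never clear it, which
  keeps the null assignment rate near zero while leaving genuinely
  separated modules (which hang far below their attachment) unaffected.

Elements on branches that never qualify stay unlabeled; the PAM stage
then attaches each unlabeled element to the cluster with the smallest
average dissimilarity, restricted (when `pam_respects_dendro`) to
clusters on its own statically cut branch and only when that average is
below the cut height. Label 0 marks unassigned proteins throughout.

**Eigenproteins, merging, kME.** A module eigenprotein is the first
principal component of the column-standardized member submatrix, with
missing cells median-imputed for this computation only, scaled to unit
variance and signed so its mean member correlation is positive. Modules
whose eigenproteins are closer than `merge_cut_height = 0.07`
(1 − Pearson) are merged iteratively with recomputation after each merge.
kME is the bicor of each protein with each eigenprotein. Membership is
then made self-consistent: proteins move to their argmax-kME module,
unassigned proteins are recruited when their best kME clears `min_kme`,
members falling below `min_kme` are released, undersized modules
dissolve, and eigenproteins/kME are recomputed each pass until a fixed
point (cap 30 passes, warning on non-convergence). `min_kme = 0.30` is
exposed because the consistency threshold is not printed in the
literature this pipeline follows; 0.30 is the conventional weak-membership
floor. Final module ids are integers ordered by size (module 1 largest).

Detection aggressiveness at `deep_split = 4` can fragment a module into
sub-clusters of the same latent factor; the merge stage reunites them
(halves of a single-factor module correlate near 0.98, far inside the
0.07 cut), which is why the pipeline's module count is driven by genuine
factors rather than by cut granularity.

## Differential abundance

Per-protein one-way fixed-effects ANOVA across groups on non-missing
cells, with Tukey–Kramer honestly-significant-difference post-hoc tests —
the Kramer form because group sizes are unequal (44/22/39). Pairwise
log2 fold changes are differences of group means. Proteins lacking two
groups with two observations are flagged `tested=False`, not dropped.
The studentized-range survival function is evaluated by Gauss–Legendre
quadrature of the classical double integral, vectorized over proteins
(agreement with the reference distribution ~1e-10; the reference
implementation is used directly for small batches and as the test
oracle). Differential abundance uses unadjusted Tukey p < 0.05 per
contrast, with BH-FDR available as an option; module-level summaries
report the member fraction below the threshold and the members' mean fold
change. Two-group designs (e.g. autopsy-confirmed cases versus
non-cases) use a two-sided pooled t test.

Abundance-tier stratification bins proteins by absolute plasma
concentration at 6.0 and 9.5 log10 pg/L (boundaries inclusive to the
intermediate tier), compares signed per-protein fold changes across tiers
by one-way ANOVA, and tests tier × upregulation independence by
chi-square without continuity correction.

## Enrichment statistics

Overrepresentation is a one-tailed Fisher exact (hypergeometric) test of
a hit list against a gene set within a background universe — the assayed
proteins, not the genome, since the universe a list was drawn from is the
defensible null. Symbols match case-insensitively with no alias
expansion. The reported p is the exact tail; the z score transforms the
*mid-p* (tail minus half the point mass) through the standard-normal
quantile, which removes the discreteness bias of the exact tail so that
z ≈ 0 at the expected overlap and z is smooth and monotone in the
evidence; p is clamped to [1e-300, 1 − 1e-16] before inversion.
Significance decisions (and BH-FDR q-values across modules) use the exact
tail. A consequence worth knowing: the exact test is conservative — its
analytic size at typical module scales (universe of hundreds, ~2.5% hit
rate per direction) is ≈0.023 at nominal 0.05 — so null rejection rates
sit below the nominal level by construction.

Module-wise trait overrepresentation takes the proteins nominally
correlated with a trait (p < 0.05, stated direction) as hits, tests each
module against the universe of tested proteins, and BH-corrects across
modules.

## Biomarker panels

The classifier is a linear support-vector machine. C is tuned by mean
stratified k-fold accuracy over a log grid 10⁻³…10³ (ties to the smallest
C, i.e. the strongest regularization that achieves the best accuracy) and
then held fixed. Recursive feature elimination drops one feature per step
by smallest absolute weight; within each training fold an elimination
path is computed and the held-out accuracy recorded at every subset size,
the optimal size maximizes mean accuracy across folds (ties to the
smaller panel), and the final membership comes from an elimination path
on the full data cut at that size. The final model is re-validated by
stratified k-fold; the panel AUC is computed from out-of-fold decision
scores. Standardization is fit inside training folds only — a test-fold
outlier cannot perturb training-fold scaling, and a test pins this.
AUC is the Mann–Whitney statistic with ties counted half; confidence
intervals are percentile bootstrap (1,000 stratified resamples) — the
simplest defensible nonparametric interval, BCa deliberately not
implemented. Candidate features are the differentially abundant proteins
for the contrast. Cross-validated accuracy of a selected panel is
optimistically biased at small n (selection and validation share folds);
the null simulations in the tests quantify this (~0.05–0.1 above chance
at n=100/group), which is why the all-noise sanity band is stated as
"within 0.15 of chance" rather than "equal to chance".

## Trait association

Global cognition is the mean of available memory and executive composite
z-scores (one missing domain falls back to the other). Neuropathology
burden sums semi-quantitative 0–3 ratings per proteinopathy over sampled
regions, or over the medial-temporal-lobe region of interest (dentate
gyrus, CA1/subiculum, CA2, CA3/CA4, entorhinal cortex, amygdala);
subregion contributions are percentages of the ROI total. Module–trait
and protein–trait correlations use Spearman's rho (midranks; t
approximation for n ≥ 10, exact permutation below — evaluated in one
matrix product over the cached table of all orderings) or bicor with a t
approximation on n − 2 df. Cells with fewer than five complete pairs are
reported untested. The sampling-to-death interval check reports bicor of
each eigenprotein with the interval plus a two-sided t test of the
interval between autopsy groups.

## Synthetic cohorts

The generator emulates the study design end-to-end. Groups default to
44 CTL / 22 RHI / 39 AD with group-specific age distributions
(70.6 ± 7.2, 57.8 ± 12.1, 67.6 ± 9.8 years) and male fractions (0.64,
1.00, 0.44). Nine modules of 60 proteins among 600 assays are driven by
standard-normal per-sample latent factors with loadings uniform in
[0.5, 1] — a single-factor module matches eigenprotein (first-PC)
semantics and gives a realistic within-module kME spread. `module_snr`
(default 2) scales the factor against unit residual noise. Group effects
are additive shifts of factor means; the study configuration shifts seven
modules in RHI (two also in AD) by 1.0 factor SD — with 22 cases against
44 controls the factor-difference SE is ≈0.26 SD, so 1.0 SD places
module contrasts in the clearly detectable regime that reported module
elevations (p < 0.01) correspond to. Per-protein planted log2 shifts
(loading × snr × Δ) are recorded in the ground truth per group pair.

Age and sex effects are per-protein Gaussian coefficients (defaults
0.01 log2/yr and 0.2 log2). Duplicate assays are re-noised copies of a
module protein sharing its UniProt accession. A quarter of the remaining
background proteins are low-abundance and LOD-censored at the
`lod_quantile` (default 0.2) of their own values — the buffer statistics
in the QC table are back-computed so the masking stage reproduces exactly
that censoring. High-missing proteins are censored at their 60% quantile,
placing them past the 50% filter deterministically. Outlier samples
(default 3, matching the reported removal event) carry baseline plus
independent noise inflated by `outlier_noise_multiplier` (default 5):
inflated independent noise, not a mean shift, because the detection
statistic is connectivity, which responds to decorrelation. Traits are
linear in realized standardized factor scores with analytic scaling to
hit target correlations; immunoassay counterparts of three assays are
affine transforms plus noise calibrated to r = 0.9; neuropathology
ratings come from an ordinal cut-point model (latent Gaussian coupled to
a module factor, thresholded at its 40/70/90% quantiles) so burden–module
correlation targets are well defined.

What the generator does *not* emulate: Olink plate/bridge batch
structure, assay-specific heteroscedasticity, longitudinal sampling,
genetic structure, non-Gaussian heavy tails, and correlated missingness
beyond the LOD mechanism. Passing tests therefore demonstrate that the
algorithms recover the structure they assume, not that real plasma data
satisfy those assumptions.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1]; collapsed biweight denominators
(near-degenerate MAD) fall back to Pearson, and fully constant pairs
return 0. Degenerate connectivity (all samples identical) returns
all-zero Z with a warning rather than dividing by zero. ANOVA with zero
within- and between-group variance reports F = 0, p = 1; Tukey contrasts
with zero difference and zero error report p = 1. Zero-variance proteins
are dropped before network construction with a note; zero-variance
eigenprotein members are dropped with a warning. Merging recomputes
eigenproteins after every single merge, making the result independent of
pair enumeration order. The pipeline CLI derives per-stage substreams
from one master seed via SHA-256, so stages can be re-run in isolation
and reproduce a full run byte-for-byte.

## Problem sizes used in the shipped checks

The validation suite runs the full pipeline on 600-protein, 108-sample
cohorts (nine 60-protein modules), null calibrations at 500 proteins ×
20 seeds, panel selection at 100 features and 100 samples per group, and
oracle comparisons on exhaustive small instances (TOM to 8×8, AUC to
n=12, hypergeometric universes to 60). These sizes were chosen so the
complete suite exercises every stage at realistic structure in a few
minutes on one core; the algorithms themselves are written for
single-block matrices up to a few thousand proteins.

## Known limitations

- The adaptive branch cut is a reimplementation of the dynamic hybrid
  *contract*, not a port: constants follow the standard sensitivity grid,
  but trees with weak, overlapping modules can cut differently than other
  implementations. The planted-recovery and null suites define the
  behavior we guarantee.
- Matrix-level bicor computes column statistics once per column rather
  than per pairwise-complete subset; with heavy structured missingness
  the two definitions can diverge (vector calls are exact).
- Bootstrap adjustment assumes linear, protein-wise covariate effects;
  shared nonlinear age effects leak into modules.
- The exact Fisher test's conservatism (above) means overrepresentation
  q-values are safe but not tight at small module counts.
- RFECV panel accuracy at small n is optimistic; treat reported CV
  accuracy as an upper bound and the null-simulation excess as its error
  bar.
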