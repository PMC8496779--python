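# Methods

## Scope and design

The package is organised around the three arms of a prospective
metabolome-wide study: (i) a matched case–control risk scan with
multiple-testing control by the effective number of tests, (ii) a
two-sample MR engine profiling an exposure's causal footprint on the
metabolome, preceded by an instrument-specificity screen, and (iii) a
profile comparison with a negative-control calibration. A synthetic
cohort generator provides data with exactly the statistical structure
the estimators assume, which is what makes sharp parameter-recovery and
calibration tests possible.

## Conditional logistic regression (matched risk scan)

For 1:1 matched sets the conditional likelihood reduces to an
intercept-free binary regression on within-pair covariate differences
`dᵢ`. We maximise `ℓ(β) = Σᵢ log σ(βᵀdᵢ)` by Newton–Raphson with
step-halving from β = 0, declaring convergence when the maximum
absolute score falls below 1e-8 (cap: 50 iterations). The likelihood is
concave, so the only failure modes are a degenerate design (all
differences zero — reported as an error) and complete separation (the
MLE diverges — reported as non-converged; a numerically "converged"
iterate with |β| > 15 is treated the same way, since a log odds ratio
of that size per 1 SD is a separation artefact, not an estimate).
Inference is Wald (observed information at the MLE), matching the
OR (95% CI) presentation convention of epidemiological tables;
likelihood-ratio intervals are not implemented.

Scans fit each metabolite pooled and per cohort; matching is within
cohort, so pooling is concatenation of the cohorts' pairs. Adjusted
models are complete-case: pairs with any missing modelled covariate are
dropped, mirroring the restriction of adjusted analyses to participants
with complete risk-factor data. Stratified analyses assign a pair to a
stratum by the *case's* covariate value (matching variables are shared
within pairs; non-matching ones differ, and the case's value is the
documented, reproducible choice), median-splitting continuous
stratifiers by default. Heterogeneity across strata uses Cochran's Q on
the stratum log-ORs with inverse-variance weights and a chi-square
(K−1) reference; strata with fewer than two informative pairs are
excluded from Q with a warning.

## Effective number of tests

ENT is the number of leading eigenvalues of the metabolite correlation
matrix (pooled cases + controls, z-scored columns) whose cumulative sum
first *strictly exceeds* 95% of total variance; "more than 95%" is read
strictly, and the equal-eigenvalue boundary case is covered by a test.
The scan threshold is `0.05/ENT` at full precision (displayed at 3
significant digits). ENT is computed per platform because targeted and
untargeted panels have very different dimensionalities and correlation
structure. The robust-hit rule is boundary-inclusive on both parts
(pooled p ≤ 0.05/ENT; per-cohort p ≤ 0.05 in ≥ 2 cohorts), and cohorts
with missing estimates count as non-significant.

## Quality control

* Limit imputation: values below the LLOQ (below the batch LOD for
  semiquantified classes — acylcarnitines, glycerophospholipids,
  sphingolipids) are set to half the relevant limit; values above the
  ULOQ are capped at the ULOQ; cells with an out-of-range internal
  standard stay missing. The operation is idempotent.
* Sparsity rule: a metabolite is excluded iff its above-limit count is
  strictly below the threshold (default 100) in at least one cohort, so
  a count of exactly 100 everywhere retains.
* Untargeted features are divided by their observed median (observed
  median becomes 1) and missing cells filled with the post-scaling
  minimum — the vendor delivery convention.
* Derived sums/ratios are appended as pseudo-metabolites from
  config-defined constituent lists; the Fischer ratio
  (Leu+Ile+Val)/(Phe+Tyr) ships as a named definition, with its
  clinical orientation (lower = hepatic dysfunction) recorded as
  metadata only. Zero denominators yield missing, never infinity.
* Log + z-scoring uses the natural log (the base cancels in z-scores —
  asserted by a test). Zero-variance columns raise by default; the
  pipeline drops them with a warning, since SD division is undefined.
  Standardisation is per cohort before pooling by default (QC is
  per-cohort in multi-centre designs), with a global mode available.
* CVs: intra-batch CV is the median over batches of 100·SD/mean among
  replicates; inter-batch CV is 100·SD/mean of the batch means.
* Cross-platform duplicates (e.g. glutamate measured on both panels)
  are never averaged; the merge keeps both columns and links them in an
  alias map, and each platform's estimate is reported separately.

## Synthetic cohort generator

Log concentrations follow a factor model
`log c = μ_m + Λf + b_m·z_BMI + ε`, with loadings drawn once per run
(`n_factors` controls correlation; 0 gives independent metabolites),
per-metabolite location μ_m ~ N(0,1), residual SD `noise_sd`, and a
standard-normal BMI z-score that both shifts metabolites (the
confounding path `b_m`, SD per SD BMI) and enters disease risk
(`bmi_logor`). Concentrations are exponentiated; the per-batch LOD is
the `lod_quantile` of the batch marginal and censored cells are
*flagged but retain their latent values*, so limit imputation is an
explicit, testable downstream step.

Case labels are assigned within pairs by the softmax of the two
members' linear predictors `η = Σ β_m z_m + β_BMI z_BMI` — exactly the
1:1 conditional likelihood — rather than by population sampling plus
matching. This makes the fitted model exactly well-specified, which is
the property the coverage and bias acceptance checks rely on.
Default sizes mirror a five-cohort consortium (1,305 pairs across five
cohorts with realistic shares, 188-metabolite targeted panel); the
default below-LOD fraction is 5% per batch, a typical order for
targeted panels (the source studies do not publish their censoring
fraction). Matching variables (age, sex, draw year) are shared within
pairs; risk-factor covariates (smoking, pack-years, alcohol,
hypertension, fasting) are drawn with plausible marginals and are
generated complete by default.

GWAS summary statistics: true per-SNP exposure effects are
N(0, `beta_exposure_sd`²) with `beta_exposure_sd` = 0.05 on the
standardized-trait scale (instruments then straddle the genome-wide
significance boundary at the default exposure n, exercising selection);
standard errors follow `1/√(2f(1−f)n)` for standardized traits;
observed betas add sampling noise at that SE. Outcome betas are
`θ·β_true + pleiotropy + noise`, where the pleiotropic term
N(`pleiotropy_mean`, `pleiotropy_sd`) is oriented by the sign of the
true exposure effect — directional pleiotropy is defined relative to
the exposure-raising allele, which is what the MR–Egger intercept
estimates. A configurable fraction of SNPs is palindromic (A/T, C/G)
and a configurable fraction of outcome rows is emitted with swapped
alleles (sign-flipped beta, complemented EAF), so harmonization has
real work on every run. A negative-control exposure is the same
machinery with θ = 0 against every metabolite.

What the generator does **not** emulate: individual-level genotypes and
real LD (an LD matrix is user-supplied or absent), batch drift beyond
per-batch limits, non-normal metabolite distributions, assay-specific
missingness mechanisms, and matching-caliper variation between cohorts
(a single exact-match scheme is used). Passing tests therefore
demonstrate correctness of the estimators under their stated
assumptions, not robustness to every feature of real cohort data.

## MR engine

Instrument selection filters exposure p < 5e-8 and greedily prunes by
LD (ascending p; retain iff R² < 0.01 with all retained). Without an LD
matrix the p-passing set is treated as pre-pruned, as published
instrument lists are, and this is logged. Harmonization aligns outcome
effects to the exposure's effect allele (sign-flip + EAF complement for
swapped alleles), drops palindromic SNPs with EAF in [0.42, 0.58] on
either side (a common convention; configurable) and drops unresolvable
mismatches, logging every drop.

IVW is the weighted through-origin regression; its SE uses a
multiplicative random-effects model — inflation by √(Q/(J−1)) when
Cochran's Q exceeds its degrees of freedom — matching the default of
the standard two-sample MR software family (the fixed- vs random-
effects choice is an explicit assumption, not something the source
analyses state). MR–Egger orients exposure betas positive, fits the
weighted regression with intercept, applies the same overdispersion
with φ = Q/(J−2) and uses t(J−2) reference distributions. The weighted
median interpolates ordered Wald ratios at cumulative weight 0.5 with
midpoint positions `s_k = Σ₁ᵏ wⱼ − w_k/2`; its SE is the SD over a
seeded parametric bootstrap (default 1,000 draws) of (β_X, β_Y) from
their stated SEs, bit-reproducible under a fixed seed. Single-SNP
analyses degrade to the Wald ratio with delta-method SE and are
flagged. Panel scans fit all three estimators per metabolite, flag
significance on the IVW p-value against the per-platform ENT threshold
and record per-metabolite failures without stopping.

## Pleiotropy screen

Per-SNP variance explained is `2f(1−f)β²` (standardized trait,
Hardy–Weinberg); when EAF is unusable the fallback is `z²/n` with
z = β/se. A candidate's instruments are summed over every panel
metabolite; the candidate is flagged pleiotropic unless it is uniquely
rank 1, and the candidate-to-best-other R² ratio is reported so the
verdict has a magnitude (the source analyses describe this judgement
only qualitatively; the rank rule makes it reproducible and the
threshold configurable). Instrument SNPs absent from a metabolite's
GWAS contribute zero and are logged.

## Profile comparison

Profiles are standardized effects (log-OR/SE for risk; β/SE for MR),
intersected by metabolite id (≥3 required), correlated by Spearman rho
with average ranks for ties and the t approximation for p (an exact
permutation p is available for n ≤ 10). Platforms are never mixed in
one correlation. The negative-control comparison reuses the machinery
and additionally counts risk-robust metabolites passing the MR
threshold under the null exposure — expected ≈ 0 in a calibrated
analysis.

## Problem sizes and numerical choices

The acceptance script and test suite use desk-scale study conditions
chosen once: 500 replicates at 1,000 pairs for CI coverage and bias
(effect size ln 1.39 per SD); 500 replicates of 100-instrument GWAS
pairs for IVW recovery at θ = −0.17 and Egger-intercept recovery at
planted pleiotropy 0.05 (after genome-wide-significant selection, which
removes near-zero exposure effects whose orientation is ambiguous); a
200-metabolite null panel and 1,000 null scan metabolites at 500 pairs
for calibration; 100 replicates of a 50-metabolite negative-control
comparison. Convergence tolerances: conditional-logistic score 1e-8;
ENT eigenvalues from `numpy.linalg.eigvalsh` (symmetric solver);
weighted-median bootstrap seeded through `numpy.random.default_rng`.

## Known limitations

n:m matched sets are out of scope (1:1 only). No LD reference panels
are bundled; LD pruning is exercised on user-supplied matrices. The
22 targeted-panel sums/ratios beyond the Fischer ratio are
config-defined rather than built in, because only the Fischer ratio has
a fully public definition. MR-PRESSO, multivariable MR and Steiger
filtering are deliberately absent: where instruments are pervasively
pleiotropic the package's position is the specificity screen's verdict,
not a corrected single-exposure estimate.
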