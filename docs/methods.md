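# Methods

## The resilience model

Cognitive resilience is operationalized as the variation in a latent
cognition dimension that is not explained by a latent brain dimension, in
amyloid-positive individuals spanning the clinical stages of Alzheimer's
disease. Both dimensions come from a canonical correlation analysis (CCA)
of a cohort's brain block **X** (regional cortical thickness, subcortical
volumes, white-matter hypointensity burden, intracranial volume) against
its cognition block **Y** (the cohort's neuropsychological battery), fitted
per cohort on z-scored variables.

CCA finds weight vectors a, b maximizing corr(Xa, Yb). Writing Sxx, Syy,
Sxy for the sample covariance blocks (n−1 denominator), the implementation
whitens and takes a singular value decomposition:

    Sxx^(−1/2) Sxy Syy^(−1/2) = U diag(r) Vᵀ

The singular values are the canonical correlations r₁ ≥ … ≥ r_K,
K = min(p, q); back-transformed singular vectors give the weights, rescaled
so each canonical variate has unit sample variance. This exposes all modes
at once and is numerically stable, unlike iterated-regression (NIPALS)
formulations; sklearn's NIPALS CCA serves as an independent cross-check in
the tests, as does a generalized-eigenproblem solver.

Per mode the package reports:

- **loadings** — correlations of each original variable with its own set's
  variate (structure coefficients);
- **redundancy** — r_k² × mean squared counterpart loading: the share of
  the cognition block's variance explained by the k-th brain variate;
- **% of co-variance explained** — two conventions, both reported:
  the eigenvalue convention 100·λ_k/Σλ with λ_k = r_k²/(1−r_k²) (default
  display, matching the R `candisc` family), and 100·r_k²/Σr_k². Neither is
  the redundancy; the distinction matters when interpreting mode shares.

Modes are sign-indeterminate, so each is oriented deterministically: if the
anchor loading (default: the mean cognition loading) is negative, the
variate/weight/loading columns of that mode are jointly negated. Higher Y₁
then always means better cognition.

Age and sex are deliberately **not** regressed out before the CCA; they are
covariates in every downstream association model instead, so their shared
variance with brain and cognition is not discarded at the latent-extraction
stage.

## Permutation inference

Significance of the first canonical correlation uses a permutation test:
the rows of Y are shuffled B times (default 10,000; 1,000 in the bundled
study runs) against a fixed X and the CCA is refit. Because a row
permutation leaves Syy and all column means unchanged, the refit reduces
exactly to the largest singular value of Wx (Xcᵀ P Yc/(n−1)) Wy with
precomputed whiteners — identical to the full refit, computed without
redundant factorizations. The p-value is the add-one Monte-Carlo estimate
(1 + #{null ≥ observed})/(B + 1), which can never be zero. A sequential
variant for later modes exists but is off the main path.

## One-model associations

Every association of interest enters one ordinary-least-squares model
together with the brain variate, rather than the classical two-step
residual approach:

    Y1 ~ X1 + Age + Sex + Education
    Y1 ~ X1 + Age + Sex + APOEi                   (ε4/ε2 carriership, 0/1)
    Y1 ~ X1 + Age + Sex + SNP + PC1 + … + PC5     (risk-oriented dosage 0–2)

Variates are standardized to unit variance; age and other continuous
covariates (education in years) are standardized per cohort, so their
coefficients are per SD. Carriership and dosages stay on their native
scales. Sensitivity models add an X1×term interaction (product formed
after standardization). The two-step residual baseline — regress Y1 on X1,
then the residual on the term — is implemented for comparison; by the
Frisch–Waugh–Lovell theorem it agrees with the one-model coefficient
exactly when the term is in-sample orthogonal to X1 and is attenuated by
1 − corr(X1, term)² otherwise, which the tests verify analytically.

Cohort coefficients are pooled by fixed-effect inverse-variance
meta-analysis (weights 1/se², normal inference; Cochran's Q computed for
reference only), and the SNP panel's meta p-values get Benjamini–Hochberg
FDR. The FDR family is the SNP panel of the run; APOE carriership
validation terms are reported uncorrected.

## Preprocessing chain

Fixed order, each step optional and logged:

1. **TMT-B imputation** — missing Trail-Making-B times are filled as
   TMT-A × R_g, with R_g the median TMT-B/TMT-A ratio over complete cases
   in the subject's diagnostic group. The median (the source procedure
   names only "a diagnostic-group specific ratio") resists the heavy right
   tail of completion times.
2. **Directionality** — every scored variable is aligned so higher = 
   better/healthier: completion times and error counts are negated;
   right-skewed burden measures (WM-hypo) map through −log(1+x). Entries
   are re-declared higher-is-better afterwards, making the step idempotent.
3. **Sparsity exclusions** — subjects with fewer than 3 cognitive tests
   (strict <) are dropped, then cognitive variables missing in strictly
   more than 50% of the remaining subjects; a variable at exactly the
   boundary stays.
4. **Outlier QC** — volumetric values outside mean ± 2 SD within
   diagnostic group are set to missing (boundary values retained; groups
   with <3 observations skipped with a warning). A one-sided
   median + 3×IQR flag for surface-hole counts identifies scans with
   potentially failed segmentations.
5. **PMM imputation** — chained predictive mean matching, single
   imputation: mean-initialize, then per sweep regress each target on the
   current predictors over its observed rows, and let each missing row copy
   the observed value of a donor drawn uniformly from the k = 5 rows with
   the nearest predictions (type-0 matching, 5 sweeps). Every imputed value
   is an observed value of the same variable; output is deterministic given
   the seed. Cognition targets use age, sex, education, diagnosis and all
   cognitive tests as predictors; volumetric targets use sex, age,
   diagnosis, the volumes, per-lobe thickness means (computed transiently —
   the whole-brain mean is excluded as an exact linear combination of
   them), WM-hypo and ICV. k and the sweep count follow common chained-
   equation defaults; the source procedure names the method only.
6. **ICV adjustment** — volumes are replaced by the residual of a fit on
   [1, ICV] plus their original mean, zeroing the sample correlation with
   head size while preserving scale for downstream z-scoring.
7. **Batch harmonization** — location/scale harmonization per variable:
   least squares on the protected biological design (age, sex, diagnosis
   dummies) plus sum-to-zero scanner-batch offsets; residuals are recentred
   by their batch offset and rescaled to the pooled residual SD. Batch
   means and variances are removed; protected-covariate slopes are
   untouched (exact on noise-free constructions). No empirical-Bayes
   shrinkage: with cohort-scale batches the per-batch moment estimates are
   stable, and the adjustable contract — not shrinkage — is what the
   downstream analysis relies on.
8. **Composites** — per-lobe (weighted by manifest region weights, e.g.
   surface area) and whole-brain thickness composites, plus an optional
   unweighted signature composite, appended as global brain columns and
   excluded from the CCA block.
9. **Genotype orientation** — protective-coded dosages map d → 2 − d so
   higher dosage always means higher risk; an involution, applied at most
   once per column.
10. **Reference z-scoring** — every cognition and MRI column standardized
    against the whole cohort (n−1 SD).

Re-running the chain on its own output with complete data is a no-op,
with three documented exceptions: ±2 SD QC re-flags tail values on any
continuous sample; composites of standardized members are a different
quantity from standardized composites; and batch-specific residual
rescaling is only approximately idempotent because rescaling breaks exact
orthogonality to the protected design. The idempotence test therefore runs
with those steps disabled, and harmonization idempotence is verified
separately in the pure-shift case, where it is exact.

## Synthetic cohorts and ground truth

The generator emulates the statistical structure the analysis assumes. Per
cohort: a brain latent b = γ_age·age_z + γ_sex·sex_z + Σθ_s g_z,s + ε
(unit variance; higher = healthier) and a cognition latent
c = ρ·b + β_edu·edu_z + Σφ_s g_z,s (+ optional ι·b·edu_z) + ε (unit
variance). Education comes from a 7-level classification mapped to years
(defaults 5–17 on a linear grid, per-cohort level probabilities); genotypes
are Binomial(2, MAF) dosages, with selected loci emitted protective-coded
to exercise risk orientation; diagnosis is derived by thresholding c at the
normal quantiles of the configured stage proportions. Regional thickness
loads linearly on b; volumes additionally load on an ICV factor; the
WM-hypo burden is log-normal in −b (so its −log(1+x) preparation is linear
in b to excellent approximation); cognitive tests load on c, some emitted
on inverted scales, including a log-normal TMT-A/TMT-B pair with a
c-dependent ratio; scanner batches add shifts and noise scalings;
missingness is MCAR at configured rates. An infeasible variance budget
(systematic variance above 1 on either latent) is a fatal error.

Because all effects live on latent scales, the population covariance of the
post-preprocessing variables is available in closed form, and the ground
truth stores (i) the implied population first canonical correlation —
computed by population CCA of the assembled covariance — and (ii) the
implied coefficient of every association term in the population regression
of Y₁ on [X₁, age, sex, term] (education per SD, SNPs per risk allele,
APOE per carriership, the latter using the exact Binomial
carrier/dosage moments). These implied values are the oracles of every
recovery test; for the log-normal TMT columns the implied computation
linearizes through the exact log-normal/latent correlation and treats the
pair's shared ratio noise as independent, so paper-scale implied values are
approximate and the recovery criteria use linear batteries, where they are
exact.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium between loci,
spatially correlated cortical maps, non-Gaussian latents, informative
(non-MCAR) missingness, site-by-covariate confounding, and longitudinal
structure.

The default study configuration mirrors a realistic two-cohort design: a
memory-clinic-like cohort (n = 1036, 68 thickness regions, 16 subcortical
volumes, WM-hypo + ICV, 16 cognitive tests, 10 scanners) and a smaller
multi-site cohort (n = 685, 11 tests, 21 scanners), sharing an 85-locus
panel (APOE-ε4/ε2-like pair with negative/positive resilience effects plus
83 loci of which 5 carry planted effects |φ| = 0.08–0.09), ρ = 0.75 and a
per-SD education effect of 0.15 on the cognition latent.

## Numerical choices

- Ridge 1e-8 added to both covariance blocks before the inverse square
  root; eigenvalue directions below the pseudo-inverse tolerance are
  dropped, not amplified, so rank-deficient blocks degrade gracefully
  (with a warning and reported effective ranks).
- Covariance and SDs use the n−1 denominator throughout.
- λ_k = r²/(1−r²) is capped at 1e12 when r reaches 1 (with a warning).
- Sum-to-zero contrasts code batch offsets; the pooled residual SD is the
  degrees-of-freedom-weighted root mean of per-batch variances; batches
  with (numerically) zero residual SD keep their residuals unscaled.
- PMM donor candidates come from an argpartition of |prediction
  differences| (ties resolved by partition order); the donor is drawn
  uniformly among them from a seeded generator.
- Monte-Carlo p-values use the add-one convention.
- Cohort CSVs are written with `%.17g` and parsed cell-wise with Python
  `float`, so a write/read cycle is bit-exact and file-based and in-memory
  pipeline runs agree bitwise.
- Every stochastic stage (imputation, permutations, simulation) draws from
  a `numpy` generator seeded from the run seed plus a stage/cohort offset,
  making full study runs reproducible to the bit.

## Problem sizes in the test suite

The suite exercises the method at sizes chosen to make its statistical
claims measurable while keeping a laptop-scale run: oracle agreement on 50
random instances (n = 100, p, q ≤ 6); permutation calibration on 500 null
datasets (n = 200, p = q = 5, B = 199) and power at a population canonical
correlation of 0.5 (n = 200, 200 replicates); education-effect recovery
over 100 replicates of two n = 1000 cohorts; FDR control on 300 replicates
of 83-locus panels; and a full deterministic double run of the default
study (B = 1000).

## Known limitations

- Single imputation only; between-imputation variance is not propagated.
- The harmonizer is location/scale without empirical-Bayes pooling; with
  very small batches its per-batch moments would be noisy (batches of ≤ 2
  are rejected outright).
- The permutation test targets the first canonical correlation; the
  sequential extension for later modes is provided but unvalidated against
  specialized step-down procedures.
- Implied oracles for log-normal test scores are linearized approximations
  (see above).
- The two-step residual baseline is included for methodological comparison
  only; its known shortcomings are the motivation for the one-model
  approach, not something the package corrects.
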