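# Methods

## Model and estimator

The engine fits recursive linear path models on observed variables — a
covariance-structure (RAM-style) formulation with no latent variables and
no mean structure; data are centered internally, so only the covariance
matrix enters the likelihood. Writing the system as y = A y + e with A
strictly lower-triangular under a topological order of the directed-edge
graph (acyclicity is enforced at spec construction) and Cov(e) = S_mat,
the implied covariance is

    Σ(θ) = (I − A)⁻¹ S_mat (I − A)⁻ᵀ.

S_mat holds one variance per variable plus free covariances: the
exogenous block is saturated by default (pairs can be constrained with
`fixed_zero`, which is how the country-indicator/sex/age covariance
constraints of the original modification step are expressed), while
residual covariances are zero unless explicitly freed. Estimation
minimizes the Wishart ML discrepancy

    F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p

over the free parameters with BFGS from per-equation OLS start values
(edge coefficients and residual variances from the sample covariance,
sample moments for the exogenous block). For any recursive model with
uncorrelated residuals these start values are already the ML optimum —
the likelihood factorizes into conditional regressions — so the
quasi-Newton step mostly certifies convergence; the optimizer matters for
constrained covariance structures. The sample covariance uses the n−1
denominator, giving the conventional χ² = (n−1)·F̂.

Numerical conditioning: the objective is evaluated on internally
unit-variance-scaled data (F and the standardized solution are invariant
to per-variable rescaling) and the estimates and their covariance are
mapped back through the exact diagonal Jacobian. Without this, raw-scale
variances spanning orders of magnitude (EPA ≈ 0.012 vs ARA ≈ 1.8) make
finite-difference gradients unreliable near the optimum.

Convergence is declared on the optimizer's own success flag or a gradient
∞-norm below 1e-5 (cap 500 iterations); both the iteration count and the
final gradient norm are reported, and non-convergence is flagged, never
silently ignored. Standard errors come from the observed information —
the numerically differentiated Hessian of ((n−1)/2)·F at the optimum.
Standardized coefficients rescale each edge by the ratio of model-implied
SDs (source/target).

Fit indices: χ² with df = p(p+1)/2 − #free and its upper-tail p;
CFI = 1 − max(χ²_M−df_M, 0)/max(χ²_B−df_B, χ²_M−df_M, 0) against the
independence baseline, whose ML solution is closed-form
(F_B = Σ ln s_ii − ln|S|); RMSEA = √(max(χ²−df, 0)/(df·(n−1))). A
saturated model (df = 0) reports χ² = 0, CFI = 1, RMSEA = 0 with an
explicit saturation flag rather than an undefined RMSEA. Pass thresholds
default to χ² p > 0.05, CFI ≥ 0.97, RMSEA ≤ 0.03 — the cutoffs used in
the study whose analysis this package reproduces.

## Effect decomposition and inference

Direct, per-path indirect, total-indirect and total effects are pure
arithmetic on the standardized coefficients: paths are enumerated
exhaustively on the DAG, each mediated path contributes the product of
its edge coefficients, and total = direct + Σ products — an identity that
holds to machine precision by construction and is also how the published
indirect cells are validated against the published direct effects
(three-mediator rows are read as *total* indirect effects, the only
reading under which every printed cell satisfies the product identity).

Inference for indirect effects defaults to the multivariate delta method:
the effect is expressed as a differentiable function of the free
parameters (through the standardized solution), its numeric gradient is
propagated through the parameter covariance, and the two-edge
independent-coefficient case reduces to the familiar Sobel formula. A
nonparametric subject-resampling bootstrap (percentile interval,
sign-crossing p) is available and preferable at small n; fewer than 100
resamples are refused. The two methods agree within a few percent at
n = 10⁴ in the test suite.

Multiplicity is controlled by the Benjamini–Hochberg step-up rule,
implemented directly from its definition (reject all p ≤ p(k*) with
k* = max{k : p(k) ≤ kq/m}); `alpha_adj` is reported as the largest
rejected p-value, matching the convention of quoting an "FDR adjusted
significance value" alongside result tables. The implementation is
cross-checked against `statsmodels.stats.multitest.multipletests` and a
brute-force evaluation of the step-up definition. Families mirror the
original analysis: one family per outcome (SBP, DBP) across that
outcome's reported effects.

## Synthetic-data generator

The generator emulates the analysis sample of the original cohort study:
n = 520 children, an additive SNP with MAF 0.29 in Hardy–Weinberg
equilibrium, fatty-acid and BMI/BP z-score marginals at the published
means/SDs, and structural effects equal to the published standardized
coefficients.

Construction is on the standardized scale: endogenous variables are drawn
recursively as z_i = Σ β_ij z_j + ε_i with residual variance 1 − β'R β
(R the implied correlation among parents), so every variable has unit
population variance and the configured standardized coefficients are the
*exact* generating truth. The genotype is drawn binomial(2, maf) per
subject — HWE by construction — and standardized analytically by its
binomial moments (G − 2p)/√(2p(1−p)) rather than empirically, so the
generating coefficient on the genotype is exact too. Variables are then
affinely rescaled to the published raw-scale marginals (the fit is
invariant to this). All randomness flows from a single seeded
`numpy.random.Generator`, making cohorts bit-reproducible.

Each cohort ships with a ground-truth ledger of generating direct
effects, all implied path products and totals (total = direct + Σ
products holds exactly).

Stratified cohorts draw the weight-status label first (Bernoulli at
prevalence 204/520 overweight/obese, the published stratum split) and
generate each stratum with its own coefficients. The published stratified
table prints the per-stratum EPA→BMI (−0.206 / +0.535) and EPA→BP direct
effects but not BMI→BP; the generator's default uses 0.140, the value
implied by the printed indirect/direct ratios (−0.029/−0.206 ≈ 0.075/0.535
≈ 0.14). Covariate effects beyond the core diagram default to zero — the
original supplementary covariate coefficients are not numerically
published — and extra covariates (binary/categorical/continuous) are
generated independently unless given paths.

What the generator does *not* emulate: genotyping-array intensity data,
the oversampling design of the fatty-acid subsample (stratum prevalence
is exposed as a knob but the sampling design is not modelled),
longitudinal waves, non-Gaussian phenotype tails, and real missingness
mechanisms (missingness is injected by tests where needed). Passing
recovery tests therefore demonstrate estimator correctness under the
modelled structure, not robustness to those real-data features.

## Phenotype and QC rules

* Additive coding counts minor (T) alleles; unknown alleles are errors,
  missing calls propagate.
* Call-rate filtering retains subjects with non-missing fraction
  *strictly greater* than the threshold (default 0.98), so 97/100 and
  98/100 are excluded and 99/100 is retained.
* The HWE test defaults to the 1-df χ² against HWE-expected counts; a
  conditional exact test (sum of heterozygote-count probabilities no
  larger than the observed one) is provided alongside. On the published
  genotype counts (266/206/48) the χ² variant gives 0.78 (p = 0.377) and
  the exact test gives p = 0.395 — exactly the published value,
  indicating the original QC used an exact-style test.
* BP consolidation: with three readings, the mean of the closest pair;
  with two, their mean if they differ by ≤5%, else missing; one reading
  is insufficient. The 5% rule's denominator is not defined in the source
  description; this implementation uses the first reading.
* z-scoring is table-driven: LMS kind z = ((x/M)^L − 1)/(LS) with the
  L→0 log limit, mean-SD kind z = (x−μ)/σ; keys are half-open
  (sex, age[, height]) bins and out-of-coverage lookups raise rather than
  extrapolate. The licensed pediatric BMI/BP references are not shipped;
  synthetic fixtures in the same file format stand in for tests, and real
  tables can be supplied as files. BP classification cutpoints (90th/95th
  percentile → prehypertension/hypertension) are stored in the table file.
* Missing values propagate; the pipeline applies listwise deletion per
  model, with the QC exclusion ledger ordered non-fasting → missing BP →
  missing covariates → missing genotype so counts sum to (input −
  analyzed).

## Pipeline

The plan runner fits the eight exposure × outcome models, decomposes the
three reported effect pairs per model (SNP→BMI, SNP→BP, FA→BP), attaches
delta-method p-values and per-outcome BH-FDR flags, and writes a
3-dp-rounded effect table plus a full-precision JSON sidecar; reports are
byte-identical across reruns on the same cohort. The fish-consumption
covariate joins exactly the EPA models when configured. The stratified
EPA analysis is run both as two separate within-stratum fits (primary,
matching the published per-stratum table) and as a pooled model with a
centered-EPA × stratum product term. Categorical covariates are
reference-coded (first level reference: six countries → five indicators,
three education levels → two).

## Problem sizes and defaults in tests

Recovery checks refit cohorts of n = 10⁵ (sampling error of a
standardized coefficient ≈ 0.003, so the ±0.02/±0.03 bands are
comfortably asymptotic); χ² calibration uses 500 replicates at the study
size n = 520; the property suites use 100 random recursive models (OLS
equivalence, tolerance 1e-6), 1000 random DAGs (path enumeration vs a
brute-force DFS oracle) and 1000 random p-vectors (BH step-up vs its
literal definition). The full suite runs in well under a minute on one
CPU.

## Known limitations

No latent variables, no FIML for missing data, no polychoric/ordinal
estimation, no modification-index search; causal identification
(confounding, cross-sectional data) is the analyst's responsibility, as
in the original study. Delta-method p-values for products are symmetric
approximations; for small samples the bootstrap is the better default.
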