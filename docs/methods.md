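# Methods

## The estimation problem

A modifiable exposure x (blood lipids, adiposity, sleep traits, …) is
measured at baseline in a prospective cohort; the outcome is the incident
diagnosis of a disease over ~a decade of follow-up. The observational Cox
association between x and the outcome is contaminated by confounding and
reverse causation. One-sample Mendelian randomization replaces x with the
part of it predicted by germline genotype: because alleles are assigned at
conception, the genetic prediction is (under the instrumental-variable
assumptions) free of classical confounding and cannot be caused by
preclinical disease.

`mrsurv` implements both analyses side by side on the same
individual-level data, plus the sensitivity estimators that probe the
exclusion-restriction assumption, driven either by user-supplied files or
by a synthetic-cohort generator whose ground truth is known exactly.

## Generative model

For scenario parameters (n, m SNPs, EAF range, LD block size/ρ, missing
rate, instrument R², confounder loadings b and c, causal log HR θ,
pleiotropy mean/SD/fraction, baseline hazard h₀, censoring horizon T and
recruitment window w, prevalent rate, seed):

* **Genotypes.** Per SNP j, EAF p_j ~ U(EAF range); dosage g_ij is the sum
  of two latent allele draws, each Bernoulli(p_j) through a Gaussian
  copula that is equicorrelated (ρ) within LD blocks — marginal
  Hardy–Weinberg is preserved while within-block dosages correlate.
  Missing cells are set uniformly at random; the generator keeps the
  complete matrix for phenotype generation and exposes the masked copy to
  the analysis.
* **Exposure.** x = Σⱼ γⱼ g_ij + b·U + ε, U ~ N(0,1) latent, ε scaled so
  Var(x) = 1. Per-SNP effects γⱼ are positive with relative sizes
  U(0.2, 1.8) — a spread, as real GWAS hits have — and are jointly
  rescaled so the realized genetic component has variance R²
  (the scenario errors out if R² + b² > 1). Binary exposures threshold
  the liability at the quantile matching the requested prevalence.
* **Survival.** Exponential proportional hazards,
  h_i = h₀·exp(θ·x_i + c·U_i + Σⱼ αⱼ g_ij) with the linear predictor
  mean-centred so h₀ is the typical per-year rate. A `pleiotropy_frac`
  subset of SNPs carries direct effects αⱼ ~ N(mean, sd) — a nonzero mean
  is directional pleiotropy, the violation MR-Egger targets. Censoring is
  administrative with staggered entry: C ~ U(T−w, T); with the defaults
  T = 12.4 y and w = 4 y the mean potential follow-up is 10.4 y,
  i.e. biobank-like. Prevalent-at-baseline status is drawn from a
  logistic model on the same centred linear predictor, so prevalent cases
  carry the same exposure signal as incident ones (this is what makes the
  incident+prevalent logistic model a meaningful robustness companion).
* **Covariates.** Sex ~ Bernoulli(0.5), age ~ U(40, 69), ten genetic PCs
  ~ N(0,1), chip ~ Bernoulli(0.5), plus stand-in columns for the
  observational adjustment sets (family history, education, income,
  deprivation, physical activity, alcohol, smoking status, SBP, lipid
  medication). None of these confound the generated exposure–outcome
  relation; they exercise the adjustment machinery. The confounder U is
  stored only on the ground-truth object, never in the cohort table.
* **Weights file.** The emulated discovery-GWAS betas are γⱼ plus noise at
  the precision of a 200,000-sample study, with SEs and p-values to
  match; instruments whose emulated p-value misses 5×10⁻⁸ are filtered
  out by the GRS builder exactly as too-weak real instruments would be.

All randomness descends from one integer seed through named child
streams; a fixed seed reproduces every file byte for byte.

**What the generator does not emulate:** realistic human LD maps or
population structure, imputation quality, covariates that actually
confound, competing risks, or multiple correlated exposures. Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to everything real biobank data can do.

## Analysis conventions

* **GRS.** Score = (Σⱼ βⱼ gⱼ)/(mean β). Filters in order: p < 5×10⁻⁸;
  optional allele harmonization (swapped alleles flip g → 2−g,
  strand-ambiguous A/T–C/G SNPs dropped); greedy LD pruning visiting SNPs
  by ascending GWAS p-value, retaining a SNP iff its squared sample
  dosage correlation with every retained SNP is ≤ 0.1 (r² is the
  conventional reading of an "LD threshold 0.1", and the pruning order
  keeps the strongest signal per clump); per-SNP mean imputation within
  the analysis sample. The signed-beta denominator follows the score's
  printed definition; it can vanish with mixed-sign betas, so that case
  raises an error and a |β| denominator is available as an option.
* **Scale of the MR estimate.** Stage two fits the z-standardized genetic
  prediction (mean 0, SD 1) for numerical stability; its coefficient
  estimates θ·sd(x̂) and is rescaled by sd(x)/sd(x̂) so the reported HR is
  per 1 SD of the exposure phenotype — algebraically the classical
  two-stage (per-unit) estimate times the exposure SD. This makes the
  estimate invariant to any positive rescaling of the GRS and, with a
  single SNP, exactly equal to that SNP's Wald ratio. Binary exposures
  use a linear probability model in stage one and the raw (not
  z-scored) prediction in stage two: "per category".
* **Second-stage standard errors** are the naive Cox/logistic errors,
  uncorrected for first-stage estimation — standard GRS practice; with
  the strong instruments used throughout (F ≫ 10) the miscalibration is
  mild, and the validation battery measures the realized CI coverage
  rather than assuming it.
* **Cox engine.** Efron tie correction, Newton–Raphson on the partial
  likelihood, convergence at relative log-likelihood change < 10⁻⁹ (max
  100 iterations), observed-information standard errors, step-halving,
  explicit errors for rank deficiency, zero events, and monotone
  likelihood. With no tied event times (the typical continuous-time case)
  a vectorized path computes the same quantities via cumulative risk-set
  sums; tied data take the general Efron path. The engines reproduce
  lifelines (Cox) and statsmodels (OLS, logistic) to ≤ 10⁻⁶ in the test
  suite, and the toy-data Newton estimate matches a 10⁻⁴-step brute-force
  grid maximization of the partial likelihood.
* **Proportional-hazards diagnostic.** Grambsch–Therneau score test:
  Schoenfeld residuals (Efron-averaged risk-set means) correlated with
  Kaplan–Meier-transformed event time; per-covariate χ²₁ statistics
  d·u_j²/(Σ(g−ḡ)²·I_jj) and a global χ²_p. Exposures failing p > 0.05
  are flagged, not dropped.
* **MR-Egger** uses fixed-effect weighted least squares (weights
  1/se_out²) with exposure betas oriented positive. No residual
  overdispersion scaling is applied: under the no-pleiotropy null with
  homogeneous effects the intercept test is then exactly nominal, which
  is what the calibration study checks. **Weighted median** interpolates
  the 50% point of normalized cumulative inverse-variance weights over
  sorted Wald ratios; its SE is a 1,000-replicate (configurable) seeded
  parametric bootstrap. **IVW** is the fixed-effect weighted mean of
  ratios, included as a cross-check estimator.
* **Quintiles.** Equal-frequency fifths by rank with stable tie-breaking,
  which guarantees group sizes equal within one (an exposure with fewer
  than five distinct values errors instead). The bottom fifth is the
  reference (HR ≡ 1, no CI). The trend line is weighted least squares of
  group log HR on group median exposure with inverse-variance weights;
  the reference group enters at log HR 0 with the largest finite weight
  among groups — its sampling variance is zero by construction, and an
  infinite weight would pin the line.
* **Multiplicity.** Bonferroni α/k. For the canonical 28-exposure family,
  0.05/28 = 0.001785… ≈ 0.0018. (Study reports sometimes quote a
  different rounded bound, e.g. 0.0013, in their abstracts; the α/k
  arithmetic is what is implemented.)
* **Subgroups** (sex, 10-year age band) refit stage one within each
  stratum and require ≥ 50 incident events, else the stratum is skipped
  with a log entry.

## Validation studies (fixed designs)

The statistical acceptance battery and `scripts/acceptance.py` use four
frozen scenarios, sized for a single CPU. Replicate counts are 100 (means
and biases) or 200 (rejection rates).

| study | n | SNPs | R² | θ | other |
|---|---|---|---|---|---|
| recovery / null calibration | 20,000 | 30 | 0.05 | log 1.2 / 0 | b = c = 0.4; h₀ = 0.006 (≈ 6% incidence, ~1,250 events) |
| Egger size | 6,000 | 15 | 0.2 | 0 | no pleiotropy; h₀ = 0.034 (≈ 28% incidence) |
| Egger power | 10,000 | 15 | 0.2 | log 2.5 | pleiotropy mean 0.0445 ≈ 30% of the per-allele mediated signal θ·γ̄, on all SNPs |
| median robustness | 10,000 | 15 | 0.2 | log 1.5 | 30% of SNPs pleiotropic, mean 0.08 |

Checks: mean two-stage HR in (1.10, 1.30) with 95% CI coverage in
[0.90, 0.98]; under θ = 0 the MR rejection rate at α = 0.05 in
[0.02, 0.09] while the observational per-SD scan on the same replicates
rejects in > 50% (it is ~100% here — the confounding MR removes); Egger
intercept rejection in [0.02, 0.09] without pleiotropy and > 50% with
directional pleiotropy; weighted-median absolute bias below both the
IVW and two-stage absolute biases under 30% invalid instruments.

Design notes. The Egger scenarios need a common outcome and strong
instruments because the intercept's standard error scales with the
per-SNP outcome SE (≈ 1/√(events·Var g)); at rare-disease event counts a
directional effect of 30% of the mediated signal is undetectable by any
method. The size scenario is the full null (θ = 0): in one-sample data
the per-SNP exposure and outcome errors are correlated (same
participants), and under a strong causal effect the fitted slope absorbs
part of that shared error, making the fixed-effect intercept test
markedly conservative — a known one-sample limitation, and the reason
Egger results from one-sample designs deserve caution. Relatedly, with
~30% cumulative incidence hazard ratios are noncollapsible: marginal
estimates are attenuated toward the null, which partially offsets
pleiotropy bias in the two-stage estimator; comparisons between
estimators in these scenarios are therefore made on rejection rates and
on bias magnitudes, which remain interpretable.

## Numerical and degenerate-input conventions

95% CIs are exp(coef ± 1.96·se) throughout. Logistic fits detect
complete/quasi-complete separation (deviance → 0 or diverging
coefficient) and raise rather than report a huge estimate. Designs are
rank-checked with pivoted QR and errors name the collinear columns; the
Cox design additionally rejects constant columns (the partial likelihood
has no intercept). Zero-variance SNPs are excluded from LD pruning with a
warning (their correlation is undefined); fully missing SNPs make mean
imputation impossible and error by name. The weighted-median drops SNPs
with zero exposure beta; fewer than three surviving instruments is an
error for Egger and the median (three points are the minimum for an
intercept-plus-slope fit to be a check at all). Follow-up exactly 3.0
years survives the "< 3 years" sensitivity exclusion (the bound is
strict). Sensitivity exclusions, pruning decisions, allele flips and
imputation counts are all logged so every analysis-set size can be
re-derived from the run log.

## Known limitations

No correction for winner's curse or sample overlap between the emulated
discovery GWAS and the analysis cohort; naive second-stage variance; no
time-varying covariates, stratified baselines, frailty, or competing
risks; sample-LD pruning rather than reference-panel LD; the generator's
covariates are non-confounding stand-ins, so the observational covariate
models are exercised structurally, not behaviourally.
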