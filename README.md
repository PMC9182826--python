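# mrsurv

One-sample Mendelian randomization (MR) for incident time-to-event
outcomes, built for epidemiologists who want to separate causal effects of
modifiable risk factors from the confounding and reverse causation that
plague observational cohort analyses.

The package implements the full analysis pattern of a prospective-biobank
MR study — and, because individual-level biobank data are restricted, a
synthetic-cohort generator with known causal ground truth so that every
stage is testable end to end.

## What it computes

**Weighted genetic risk score.** From a GWAS weight file (instruments at
p < 5×10⁻⁸, LD-pruned at r² ≤ 0.1, missing dosages mean-imputed):

```
GRS_i = (β₁·g_i1 + β₂·g_i2 + … + β_n·g_in) / [(β₁ + β₂ + … + β_n)/n]
```

**Two-stage MR.** Stage one: linear regression of the exposure phenotype x
on the GRS, adjusting for sex, age, ten genetic principal components, and
genotyping chip; the genetic prediction x̂ is z-standardized. Stage two:
Cox proportional hazards of the incident outcome on the standardized
prediction (same covariates, prevalent cases excluded), reported as a
hazard ratio per 1 SD of the exposure (per category for binary
exposures); a logistic model on incident-plus-prevalent case status is
the robustness companion. Instrument strength is the stage-one
F-statistic (F < 10 flags a weak instrument).

**Pleiotropy-robust sensitivity estimators** on per-SNP summary
associations (β̂_exp from linear regression, β̂_out as a Cox log HR, same
covariates): inverse-variance-weighted (IVW) mean of Wald ratios
β̂_out/β̂_exp; MR-Egger regression, whose intercept tests directional
horizontal pleiotropy; and the weighted median of Wald ratios, consistent
while ≥ 50% of weight comes from valid instruments.

**Observational scan.** Per-exposure Cox models under declared covariate
adjustment sets, hazard ratios rescaled to reporting units, a
Grambsch–Therneau proportional-hazards diagnostic, Bonferroni correction
(α/k, e.g. 0.05/28 = 0.0018), equal-frequency fifths with an
inverse-variance-weighted log-linear trend, and reverse-causation
sensitivity exclusions (lipid-medication users; follow-up < 3 years).

**Synthetic cohorts.** Genotypes under Hardy–Weinberg with optional
copula-induced LD blocks; exposure x = Σγⱼgⱼ + b·U + ε with a chosen
instrument R², latent confounder U, and optional liability-threshold
binary phenotypes; exponential proportional-hazards event times with
hazard h₀·exp(θx + c·U + Σαⱼgⱼ) (directional pleiotropy via αⱼ),
staggered-entry administrative censoring, and prevalent-case flags. The
generator records everything it used (γ, α, θ, U) for recovery testing.

## Worked example

`examples/04_mr_analysis.py` simulates two 12,000-person cohorts with an
identical strong confounder (affecting exposure and hazard) — one with no
causal effect and one with a true HR of 1.4 per SD — and runs the full
battery:

```
=== confounded null (true HR 1.0) ===
stage-one F = 1101 (R^2 from GRS = 0.084; weak instrument: False)
two_stage_cox       HR  0.99 (0.85-1.15) per 1-SD
two_stage_logistic  OR  0.99 (0.83-1.17) per 1-SD
ivw                 HR  0.98 (0.84-1.14) per 1-SD
mr_egger            HR  0.88 (0.64-1.21) per 1-SD  intercept +0.0128 (p = 0.48)
weighted_median     HR  0.91 (0.73-1.12) per 1-SD

=== real effect (true HR 1.4) ===
stage-one F = 1101 (R^2 from GRS = 0.084; weak instrument: False)
two_stage_cox       HR  1.33 (1.15-1.55) per 1-SD
...
```

On the same null cohort the *observational* scan
(`examples/03_observational_scan.py`) reports HR 1.31 (1.25–1.37),
p ≈ 10⁻³¹ — a purely confounded association that every genetic estimator
correctly declines to find (all CIs cover 1, Egger intercept p = 0.48).
In the effect cohort all estimators centre near the true HR 1.4.

The other examples cover cohort simulation, GRS construction with LD
pruning and imputation, the observational scan with fifths/trend, and the
config-driven end-to-end pipeline (also available as the `mrsurv` CLI:
`mrsurv all --config cfg.yaml --out run/`).

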