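"""Synthetic cohort generator with known causal ground truth.

Emulates the three inputs a one-sample Mendelian-randomization study of an
incident outcome consumes — a GWAS weight file, a genotype dosage matrix,
and a baseline cohort table — from a single :class:`SimulationScenario`:

* genotypes: per-SNP binomial(2, EAF) dosages under Hardy–Weinberg, with
  optional within-block linkage disequilibrium induced by a Gaussian copula
  on the latent allele draws (marginal HWE preserved), and uniform random
  missingness;
* exposure: x = sum_j gamma_j g_j + b*U + eps, with the per-SNP effects
  scaled so the SNPs jointly explain ``instrument_r2`` of a unit-variance
  exposure, U a latent standard-normal confounder, and an optional
  liability-threshold dichotomization for binary phenotypes;
* survival: exponential proportional-hazards event times with hazard
  h0 * exp(theta*x + c*U + sum_j alpha_j g_j), staggered-entry
  administrative censoring, and a prevalent-at-baseline flag whose risk
  follows the same linear predictor (for the logistic robustness model);
* covariates: sex, age (uniform 40-69), ten genetic principal components,
  genotyping chip, and stand-in lifestyle/socioeconomic adjustment columns
  for the observational covariate models.

The confounder U is stored only on :class:`GroundTruth`, never in the
cohort table, so downstream analyses cannot accidentally adjust for it.
All randomness flows from one integer seed through named child streams, so
a fixed seed yields byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grs import GenotypePanel

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "SimulatedCohort",
    "generate_genotypes",
    "generate_exposure",
    "generate_survival",
    "generate_covariates",
    "simulate_cohort",
    "make_weight_table",
]

OBS_COVARIATE_COLUMNS = [
    "family_history",
    "education",
    "income",
    "townsend",
    "mets",
    "alcohol",
    "smoking_status",
    "sbp",
]


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the generative model.

    Effects are on the scale of a unit-variance continuous exposure and a
    per-year baseline hazard; ``causal_log_hr`` is the log hazard ratio per
    1-SD exposure, ``pleiotropy_mean/sd`` are per-allele direct log-hazard
    effects carried by a ``pleiotropy_frac`` fraction of SNPs.
    """

    n_samples: int = 10_000
    n_snps: int = 30
    eaf_range: tuple[float, float] = (0.1, 0.9)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    instrument_r2: float = 0.05
    confounder_effect_exposure: float = 0.4
    confounder_log_hr: float = 0.4
    causal_log_hr: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    baseline_hazard: float = 0.006
    admin_censor_years: float = 12.4
    recruit_window_years: float = 4.0
    prevalent_rate: float = 0.0
    binary_exposure: bool = False
    binary_prevalence: float = 0.25
    seed: int = 0

    def validate(self):
        problems = []
        if self.n_samples < 1 or self.n_snps < 1:
            problems.append("n_samples and n_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            problems.append("eaf_range must lie strictly inside (0,1)")
        if self.ld_block_size < 1:
            problems.append("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            problems.append("ld_rho must be in [0,1)")
        for name in ("missing_rate", "instrument_r2", "prevalent_rate", "pleiotropy_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0) and not (name == "pleiotropy_frac" and v == 1.0):
                problems.append(f"{name} must be in [0,1)")
        if self.instrument_r2 + self.confounder_effect_exposure**2 >= 1.0:
            problems.append(
                "variance decomposition impossible: instrument_r2 + confounder^2 >= 1"
            )
        if self.baseline_hazard <= 0:
            problems.append("baseline_hazard must be > 0")
        if self.admin_censor_years <= 0:
            problems.append("admin_censor_years must be > 0")
        if not (0.0 <= self.recruit_window_years <= self.admin_censor_years):
            problems.append("recruit_window_years must be in [0, admin_censor_years]")
        if self.binary_exposure and not (0.0 < self.binary_prevalence < 1.0):
            problems.append("binary_prevalence must be in (0,1)")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))
        return self

    def with_(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Exactly the quantities used in generation, for recovery tests."""

    gamma: np.ndarray | None = None  # per-SNP exposure effects (per allele)
    alpha: np.ndarray | None = None  # per-SNP direct log-hazard effects
    theta: float = 0.0  # causal log HR per 1-SD exposure
    confounder_effect_exposure: float = 0.0
    confounder_log_hr: float = 0.0
    u: np.ndarray | None = None  # latent confounder values
    latent_exposure: np.ndarray | None = None  # pre-threshold liability
    complete_dosages: np.ndarray | None = field(default=None, repr=False)


def _streams(seed, *names):
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_genotypes(scenario: SimulationScenario, rng=None) -> GenotypePanel:
    """Draw the dosage matrix.

    Each SNP is binomial(2, EAF) marginally; within an LD block the two
    latent allele draws are correlated across SNPs through an equicorrelated
    Gaussian copula with parameter ``ld_rho``. Missing cells (NaN) are set
    uniformly at random at ``missing_rate``; the fully observed matrix is
    kept on the returned panel's ``complete`` attribute for downstream
    phenotype generation.
    """
    scenario.validate()
    if rng is None:
        rng = _streams(scenario.seed, "genotypes")["genotypes"]
    n, m = scenario.n_samples, scenario.n_snps
    eaf = rng.uniform(*scenario.eaf_range, size=m)
    rho = scenario.ld_rho
    bs = scenario.ld_block_size

    if rho == 0.0 or bs == 1:
        dosages = rng.binomial(2, eaf, size=(n, m)).astype(float)
    else:
        dosages = np.zeros((n, m))
        thresh = eaf  # allele present iff copula uniform < EAF
        for _hap in range(2):
            z_shared = rng.standard_normal((n, (m + bs - 1) // bs))
            z_own = rng.standard_normal((n, m))
            blocks = np.repeat(np.arange((m + bs - 1) // bs), bs)[:m]
            z = np.sqrt(rho) * z_shared[:, blocks] + np.sqrt(1 - rho) * z_own
            from scipy.stats import norm

            u = norm.cdf(z)
            dosages += (u < thresh).astype(float)

    complete = dosages.copy()
    mask = None
    if scenario.missing_rate > 0:
        mask = rng.random((n, m)) < scenario.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    snp_ids = [f"rs{j + 1:05d}" for j in range(m)]
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    panel = GenotypePanel(
        dosages=dosages,
        sample_ids=pd.Index(sample_ids, name="sample_id"),
        snp_ids=pd.Index(snp_ids, name="snp_id"),
        eaf=eaf,
    )
    panel.complete = complete
    return panel


def generate_exposure(panel, scenario: SimulationScenario, truth=None, rng=None):
    """Generate the exposure phenotype and fill in its ground truth.

    Per-SNP effects gamma_j are positive with relative sizes uniform on
    (0.2, 1.8) (so the per-SNP effect spectrum has spread, as real GWAS hits
    do), jointly rescaled so the realized genetic component has variance
    ``instrument_r2``; the confounder and noise components complete a
    unit-variance exposure. Binary exposures are dichotomized at the
    liability threshold matching ``binary_prevalence``.
    """
    scenario.validate()
    if rng is None:
        rng = _streams(scenario.seed, "exposure")["exposure"]
    if truth is None:
        truth = GroundTruth()
    G = getattr(panel, "complete", None)
    if G is None:
        G = panel.dosages
        if np.isnan(G).any():
            raise ValueError("panel has missing dosages and no complete copy")
    n, m = G.shape
    b = scenario.confounder_effect_exposure
    r2 = scenario.instrument_r2
    resid_var = 1.0 - r2 - b * b
    if resid_var < 0:
        raise ValueError("variance components exceed 1")

    u = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    if r2 > 0:
        gamma = rng.uniform(0.2, 1.8, size=m)
        raw = G @ gamma
        sd_raw = raw.std()
        if sd_raw == 0:
            raise ValueError("degenerate genotypes: genetic score has zero variance")
        gamma = gamma * np.sqrt(r2) / sd_raw
    else:
        gamma = np.zeros(m)
    genetic = G @ gamma
    x = genetic - genetic.mean() + b * u + np.sqrt(resid_var) * eps

    truth.gamma = gamma
    truth.u = u
    truth.confounder_effect_exposure = b
    truth.latent_exposure = x
    truth.complete_dosages = G

    if scenario.binary_exposure:
        cut = np.quantile(x, 1.0 - scenario.binary_prevalence)
        x_out = (x > cut).astype(float)
    else:
        x_out = x
    return x_out, truth


def generate_survival(panel, exposure, scenario: SimulationScenario, truth, rng=None):
    """Exponential proportional-hazards event times with staggered-entry
    administrative censoring and a prevalent-at-baseline flag.

    hazard_i = h0 * exp(theta*x_i + c*U_i + sum_j alpha_j g_ij), with the
    linear predictor mean-centred so h0 is the typical per-year rate.
    Censoring time ~ Uniform(T - w, T) with T the administrative horizon
    and w the recruitment window. Prevalent status is drawn from a logistic
    model on the same (centred) linear predictor, so prevalent cases carry
    the same exposure signal as incident ones.
    """
    scenario.validate()
    if scenario.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if rng is None:
        rng = _streams(scenario.seed, "survival")["survival"]
    G = truth.complete_dosages
    n, m = G.shape
    x = np.asarray(exposure, dtype=float)

    k_pleio = int(round(scenario.pleiotropy_frac * m))
    alpha = np.zeros(m)
    if k_pleio > 0 and (scenario.pleiotropy_mean != 0 or scenario.pleiotropy_sd != 0):
        which = rng.choice(m, size=k_pleio, replace=False)
        alpha[which] = rng.normal(
            scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=k_pleio
        )
    theta = scenario.causal_log_hr
    c = scenario.confounder_log_hr
    lp = theta * x + c * truth.u + G @ alpha
    lp = lp - lp.mean()
    rate = scenario.baseline_hazard * np.exp(lp)

    t_event = rng.exponential(1.0 / rate)
    T, w = scenario.admin_censor_years, scenario.recruit_window_years
    censor = rng.uniform(T - w, T, size=n) if w > 0 else np.full(n, T)
    followup = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    if scenario.prevalent_rate > 0:
        base_logit = np.log(scenario.prevalent_rate / (1 - scenario.prevalent_rate))
        p_prev = 1.0 / (1.0 + np.exp(-(base_logit + lp)))
        prevalent = (rng.random(n) < p_prev).astype(int)
    else:
        prevalent = np.zeros(n, dtype=int)

    truth.alpha = alpha
    truth.theta = theta
    truth.confounder_log_hr = c
    return followup, event, prevalent


def generate_covariates(scenario: SimulationScenario, rng=None) -> pd.DataFrame:
    """Baseline covariate columns: the MR adjustment set (sex, age, ten
    genetic PCs, genotyping chip) plus stand-in columns for the
    observational covariate models. None of these confound the generated
    exposure-outcome relation; they exercise the adjustment machinery."""
    scenario.validate()
    if rng is None:
        rng = _streams(scenario.seed, "covariates")["covariates"]
    n = scenario.n_samples
    df = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(40.0, 69.0, size=n),
        }
    )
    for k in range(1, 11):
        df[f"pc{k}"] = rng.standard_normal(n)
    df["chip"] = rng.integers(0, 2, size=n)
    df["family_history"] = (rng.random(n) < 0.6).astype(int)
    df["education"] = rng.integers(0, 6, size=n)
    df["income"] = rng.integers(0, 5, size=n)
    df["townsend"] = rng.standard_normal(n)
    df["mets"] = rng.exponential(20.0, size=n)
    df["alcohol"] = rng.exponential(10.0, size=n)
    df["smoking_status"] = rng.integers(0, 3, size=n)
    df["sbp"] = rng.normal(140.0, 19.6, size=n)
    df["lipid_med"] = (rng.random(n) < 0.10).astype(int)
    return df


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    panel: GenotypePanel
    cohort: pd.DataFrame
    weights: pd.DataFrame
    truth: GroundTruth
    scenario: SimulationScenario

    @property
    def exposure_column(self):
        return "exposure_sim"


def make_weight_table(
    panel, truth, rng=None, gwas_n: int = 200_000, noise_scale: float = 1.0
) -> pd.DataFrame:
    """Emulated external-GWAS weight file for the generated SNPs.

    Reported betas are the true per-allele exposure effects plus sampling
    noise at the precision of a ``gwas_n``-sized discovery study; SEs and
    p-values follow. Alleles are written pre-aligned (effect allele = the
    counted allele, non-ambiguous pairs).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = len(panel.snp_ids)
    eaf = panel.eaf if panel.eaf is not None else np.full(m, 0.5)
    var_g = 2.0 * eaf * (1.0 - eaf)
    se = noise_scale / np.sqrt(gwas_n * var_g)
    gamma = truth.gamma if truth.gamma is not None else np.zeros(m)
    beta = gamma + rng.normal(0.0, se)
    from scipy import stats as _st

    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = np.clip(2.0 * _st.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "eaf": eaf,
        }
    )


def simulate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Run the full generator: genotypes -> exposure -> survival ->
    covariates -> weight table, all from the scenario's single seed."""
    scenario.validate()
    rngs = _streams(
        scenario.seed, "genotypes", "exposure", "survival", "covariates", "weights"
    )
    panel = generate_genotypes(scenario, rngs["genotypes"])
    exposure, truth = generate_exposure(panel, scenario, rng=rngs["exposure"])
    followup, event, prevalent = generate_survival(
        panel, exposure, scenario, truth, rng=rngs["survival"]
    )
    cov = generate_covariates(scenario, rngs["covariates"])
    cohort = pd.DataFrame({"sample_id": panel.sample_ids})
    cohort = pd.concat([cohort, cov], axis=1)
    cohort["exposure_sim"] = exposure
    cohort["followup_years"] = followup
    cohort["event"] = event
    cohort["prevalent"] = prevalent
    weights = make_weight_table(panel, truth, rngs["weights"])
    return SimulatedCohort(
        panel=panel, cohort=cohort, weights=weights, truth=truth, scenario=scenario
    )
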