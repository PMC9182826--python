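"""One-sample Mendelian randomization with a time-to-event outcome.

Stage one regresses the exposure phenotype on the weighted GRS (adjusting
for sex, age, ten genetic principal components, and genotyping chip) and
forms the genetically predicted exposure; stage two fits a Cox model of
the incident outcome on the z-standardized prediction (same covariates),
and a logistic model on incident-plus-prevalent case status as a
robustness check. Reported effects are hazard/odds ratios per 1 SD of the
exposure phenotype for continuous exposures and per category for binary
ones.

Scale convention: the z-scored prediction (mean 0, SD 1) is what enters
the second-stage fit; its coefficient estimates theta * sd(x_hat), so it
is rescaled by sd(exposure)/sd(x_hat) to the per-exposure-SD scale. This
is algebraically the classical two-stage estimate (coefficient per unit
of exposure) multiplied by the exposure SD, and it makes the estimate
invariant to any positive rescaling of the GRS.

Pleiotropy-robust sensitivity estimators operate on per-SNP summary
associations (exposure side: linear regression; outcome side: Cox log HR;
both with the MR covariate set):

* :func:`ivw` — inverse-variance-weighted mean of per-SNP Wald ratios;
* :func:`mr_egger` — weighted regression with a free intercept; a nonzero
  intercept indicates directional horizontal pleiotropy;
* :func:`weighted_median` — weighted median of Wald ratios, consistent
  when at least half the weight comes from valid instruments; SE by
  seeded parametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import engines
from .observational import (
    DEFAULT_COVARIATE_MODELS,
    CovariateModel,
    QuintileResult,
    build_design,
    quintile_analysis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageOneFit",
    "MrEstimate",
    "SnpSummary",
    "stage_one",
    "stage_two_cox",
    "stage_two_logistic",
    "per_snp_associations",
    "ivw",
    "mr_egger",
    "weighted_median",
    "quintiles_of_prediction",
    "subgroup_mr",
    "run_mr",
]

_Z95 = 1.959963984540054
MR_MODEL = DEFAULT_COVARIATE_MODELS["mr"]
WEAK_INSTRUMENT_F = 10.0


@dataclass
class StageOneFit:
    """First-stage linear fit of exposure on GRS + covariates."""

    fit: engines.LinearFit
    prediction: np.ndarray  # genetic prediction on the exposure scale
    standardized: np.ndarray  # z-scored prediction (mean 0, SD 1)
    prediction_sd: float  # sd of the raw genetic prediction
    exposure_sd: float  # sd of the observed exposure phenotype
    f_stat: float
    r2_grs: float  # partial R^2 attributable to the GRS term
    n: int
    sample_index: pd.Index | None = None
    binary: bool = False

    @property
    def weak(self):
        return self.f_stat < WEAK_INSTRUMENT_F


@dataclass
class MrEstimate:
    """One estimator's output on its ratio scale (HR or OR)."""

    estimator: str
    scale: str  # "per 1-SD" or "per category"
    ratio_measure: str  # "HR" or "OR"
    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    log_estimate: float
    log_se: float
    n: int
    n_events: int | None = None
    f_stat: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "estimator": self.estimator,
            "scale": self.scale,
            "measure": self.ratio_measure,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalue,
            "log_estimate": self.log_estimate,
            "log_se": self.log_se,
            "n": self.n,
            "events": self.n_events,
            "F": self.f_stat,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


def _from_log(estimator, scale, measure, b, se, n, **kw) -> MrEstimate:
    return MrEstimate(
        estimator=estimator,
        scale=scale,
        ratio_measure=measure,
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z95 * se)),
        ci_high=float(np.exp(b + _Z95 * se)),
        pvalue=float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else 0.0,
        log_estimate=float(b),
        log_se=float(se),
        n=n,
        **kw,
    )


def stage_one(
    cohort: pd.DataFrame,
    grs: pd.Series,
    exposure: str,
    model: CovariateModel = MR_MODEL,
    binary: bool | None = None,
) -> StageOneFit:
    """Fit exposure ~ GRS + covariates and form the genetic prediction.

    Complete cases for the exposure are used. The genetic prediction is
    the GRS term's fitted contribution (affine in the GRS); for continuous
    exposures its z-scored version is what stage two consumes. An
    F-statistic below 10 triggers a weak-instrument warning but the
    analysis proceeds.
    """
    aligned = grs.reindex(cohort["sample_id"])
    if aligned.isna().any():
        raise ValueError("GRS missing for some cohort samples")
    keep = cohort[exposure].notna().to_numpy()
    sub = cohort.loc[keep]
    g = aligned.to_numpy(dtype=float)[keep]
    y = sub[exposure].to_numpy(dtype=float)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    X, names = build_design(sub, model, extra={"grs": g})
    fit = engines.fit_linear(y, X, terms=names, f_term="grs")
    if fit.f_stat is not None and fit.f_stat < WEAK_INSTRUMENT_F:
        logger.warning(
            "weak instrument for %s: F = %.2f < %.0f", exposure, fit.f_stat, WEAK_INSTRUMENT_F
        )
    b_grs, _ = fit["grs"]
    pred = b_grs * g  # affine shift absorbed by standardization / Cox
    sd_pred = float(pred.std())
    if sd_pred == 0.0:
        standardized = np.zeros_like(pred)
    else:
        standardized = (pred - pred.mean()) / sd_pred

    # partial R^2 of the GRS term: squared semi-partial correlation
    dof = fit.n - len(fit.terms)
    t2 = fit.f_stat if fit.f_stat is not None else 0.0
    r2_grs = float(t2 / (t2 + dof))

    return StageOneFit(
        fit=fit,
        prediction=pred,
        standardized=standardized,
        prediction_sd=sd_pred,
        exposure_sd=float(y.std()),
        f_stat=float(fit.f_stat),
        r2_grs=r2_grs,
        n=fit.n,
        sample_index=pd.Index(sub["sample_id"]),
        binary=bool(binary),
    )


def _stage_two_scale(s1: StageOneFit):
    """(regressor, rescale factor, scale label) for the second stage."""
    if s1.binary:
        # per-category: raw genetic prediction, coefficient used as-is
        return s1.prediction, 1.0, "per category"
    if s1.prediction_sd == 0.0:
        raise ValueError("zero-variance genetic prediction; cannot run stage two")
    return s1.standardized, s1.exposure_sd / s1.prediction_sd, "per 1-SD"


def stage_two_cox(
    s1: StageOneFit,
    cohort: pd.DataFrame,
    model: CovariateModel = MR_MODEL,
) -> MrEstimate:
    """Cox fit of the incident outcome on the genetic prediction.

    Prevalent cases are excluded; the hazard ratio is reported per 1 SD of
    the exposure (continuous) or per category (binary). Standard errors
    are the naive second-stage errors (no correction for first-stage
    estimation)."""
    z, rescale, scale = _stage_two_scale(s1)
    sub = cohort.set_index("sample_id").loc[s1.sample_index].reset_index()
    if "prevalent" in sub.columns:
        keep = (sub["prevalent"] == 0).to_numpy()
    else:
        keep = np.ones(len(sub), dtype=bool)
    sub2 = sub.loc[keep]
    X, names = build_design(sub2, model, extra={"pred": z[keep]})
    fit = engines.fit_cox(
        sub2["followup_years"].to_numpy(), sub2["event"].to_numpy(), X, terms=names
    )
    b, se = fit["pred"]
    return _from_log(
        "two_stage_cox",
        scale,
        "HR",
        b * rescale,
        se * abs(rescale),
        fit.n,
        n_events=fit.n_events,
        f_stat=s1.f_stat,
    )


def stage_two_logistic(
    s1: StageOneFit,
    cohort: pd.DataFrame,
    model: CovariateModel = MR_MODEL,
) -> MrEstimate:
    """Logistic fit on all cases (incident or prevalent) vs non-cases."""
    z, rescale, scale = _stage_two_scale(s1)
    sub = cohort.set_index("sample_id").loc[s1.sample_index].reset_index()
    case = sub["event"].to_numpy()
    if "prevalent" in sub.columns:
        case = ((case == 1) | (sub["prevalent"].to_numpy() == 1)).astype(int)
    X, names = build_design(sub, model, extra={"pred": z})
    fit = engines.fit_logistic(case, X, terms=names)
    b, se = fit["pred"]
    return _from_log(
        "two_stage_logistic",
        scale,
        "OR",
        b * rescale,
        se * abs(rescale),
        fit.n,
        n_events=int(case.sum()),
        f_stat=s1.f_stat,
    )


@dataclass
class SnpSummary:
    """Per-SNP exposure and outcome associations on a shared SNP set."""

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray  # log HR per allele
    se_out: np.ndarray
    exposure_sd: float = 1.0
    dropped: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.snp_ids)

    def oriented(self) -> "SnpSummary":
        """Flip signs so every exposure beta is positive."""
        s = np.sign(self.beta_exp)
        s[s == 0] = 1.0
        return SnpSummary(
            snp_ids=list(self.snp_ids),
            beta_exp=self.beta_exp * s,
            se_exp=self.se_exp.copy(),
            beta_out=self.beta_out * s,
            se_out=self.se_out.copy(),
            exposure_sd=self.exposure_sd,
            dropped=list(self.dropped),
        )


def per_snp_associations(
    panel,
    cohort: pd.DataFrame,
    exposure: str,
    snp_ids=None,
    model: CovariateModel = MR_MODEL,
) -> SnpSummary:
    """Per-SNP beta_exp (linear) and beta_out (Cox log HR), both adjusted
    for the MR covariate set. SNPs whose fits fail are dropped with a log
    entry; fewer than 3 survivors is an error (the sensitivity estimators
    need at least 3 instruments)."""
    if snp_ids is None:
        snp_ids = list(panel.snp_ids)
    sub = cohort.loc[cohort[exposure].notna()]
    y = sub[exposure].to_numpy(dtype=float)
    row_idx = panel.sample_ids.get_indexer(sub["sample_id"])
    if (row_idx < 0).any():
        raise ValueError("cohort contains samples absent from the panel")
    inc = (
        (sub["prevalent"] == 0).to_numpy()
        if "prevalent" in sub.columns
        else np.ones(len(sub), dtype=bool)
    )
    t = sub["followup_years"].to_numpy()
    d = sub["event"].to_numpy()

    ids, be, se_e, bo, se_o, dropped = [], [], [], [], [], []
    X_cov, cov_names = build_design(sub, model)
    for sid in snp_ids:
        j = panel.snp_ids.get_loc(sid)
        g = panel.dosages[row_idx, j]
        if np.isnan(g).any():
            raise ValueError("panel has missing dosages; impute first")
        try:
            Xe = np.column_stack([g, X_cov])
            fe = engines.fit_linear(y, Xe, terms=["snp"] + cov_names)
            Xo = np.column_stack([g[inc], X_cov[inc]])
            fo = engines.fit_cox(t[inc], d[inc], Xo, terms=["snp"] + cov_names)
        except (engines.RankDeficientError, engines.ConvergenceError, ValueError) as exc:
            logger.warning("per-SNP fit failed for %s: %s", sid, exc)
            dropped.append(sid)
            continue
        b1, s1_ = fe["snp"]
        b2, s2_ = fo["snp"]
        ids.append(sid)
        be.append(b1)
        se_e.append(s1_)
        bo.append(b2)
        se_o.append(s2_)
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} SNPs with usable associations; need at least 3"
        )
    return SnpSummary(
        snp_ids=ids,
        beta_exp=np.array(be),
        se_exp=np.array(se_e),
        beta_out=np.array(bo),
        se_out=np.array(se_o),
        exposure_sd=float(y.std()),
        dropped=dropped,
    )


def _ratio_estimates(s: SnpSummary, min_snps: int = 3):
    """Per-SNP Wald ratios and first-order delta-method weights."""
    nz = s.beta_exp != 0.0
    dropped = [sid for sid, ok in zip(s.snp_ids, nz) if not ok]
    if dropped:
        logger.warning("dropping %d SNPs with zero exposure beta", len(dropped))
    if nz.sum() < min_snps:
        raise ValueError(f"fewer than {min_snps} SNPs with nonzero exposure betas")
    ratio = s.beta_out[nz] / s.beta_exp[nz]
    var = (s.se_out[nz] / s.beta_exp[nz]) ** 2
    return ratio, 1.0 / var, nz


def ivw(snp_summary: SnpSummary, per_sd: bool = True) -> MrEstimate:
    """Inverse-variance-weighted mean of per-SNP Wald ratios (fixed
    effect) — equivalently the zero-intercept weighted regression slope."""
    s = snp_summary.oriented()
    if len(s) < 2:
        raise ValueError("IVW needs at least 2 SNPs")
    ratio, w, _ = _ratio_estimates(s, min_snps=2)
    b = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    scale_f = s.exposure_sd if per_sd else 1.0
    return _from_log("ivw", "per 1-SD" if per_sd else "per unit", "HR", b * scale_f, se * scale_f, len(s))


def mr_egger(snp_summary: SnpSummary, per_sd: bool = True) -> MrEstimate:
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with a free intercept (weights 1/se_out^2, fixed effect).

    The slope is the pleiotropy-adjusted causal log HR; the intercept
    estimates the average directional pleiotropic effect, and its
    two-sided p-value is the standard horizontal-pleiotropy diagnostic."""
    s = snp_summary.oriented()
    if len(s) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    x, y0, w = s.beta_exp, s.beta_out, 1.0 / s.se_out**2
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate exposure-beta spread: Egger slope unidentified")
    xbar = np.average(x, weights=w)
    ybar = np.average(y0, weights=w)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    slope = float(np.sum(w * (x - xbar) * (y0 - ybar)) / sxx)
    inter = float(ybar - slope * xbar)
    se_slope = float(np.sqrt(1.0 / sxx))
    se_inter = float(np.sqrt(1.0 / np.sum(w) + xbar**2 / sxx))
    p_inter = float(2.0 * stats.norm.sf(abs(inter / se_inter)))
    scale_f = s.exposure_sd if per_sd else 1.0
    est = _from_log(
        "mr_egger",
        "per 1-SD" if per_sd else "per unit",
        "HR",
        slope * scale_f,
        se_slope * scale_f,
        len(s),
        egger_intercept=inter,
        egger_intercept_se=se_inter,
        egger_intercept_p=p_inter,
    )
    return est


def weighted_median(
    snp_summary: SnpSummary, n_boot: int = 1000, seed: int = 0, per_sd: bool = True
) -> MrEstimate:
    """Weighted median of per-SNP Wald ratios.

    Weights are inverse delta-method variances; the estimate interpolates
    the 50% point of the normalized cumulative weights over the sorted
    ratios. The SE comes from a parametric bootstrap: per-SNP betas are
    resampled from their normal sampling distributions ``n_boot`` times
    with a fixed seed."""
    s = snp_summary.oriented()
    if len(s) < 3:
        raise ValueError("weighted median needs at least 3 SNPs")

    def wm(bx, by, se_out):
        nz = bx != 0.0
        if nz.sum() == 0:
            return np.nan
        ratio = by[nz] / bx[nz]
        w = (bx[nz] / se_out[nz]) ** 2
        order = np.argsort(ratio)
        r = ratio[order]
        w = w[order]
        cw = np.cumsum(w) - 0.5 * w
        cw = cw / w.sum()
        if cw[0] >= 0.5:
            return float(r[0])
        if cw[-1] <= 0.5:
            return float(r[-1])
        return float(np.interp(0.5, cw, r))

    ratio, w, nz = _ratio_estimates(s)
    bx, by = s.beta_exp[nz], s.beta_out[nz]
    sex, seo = s.se_exp[nz], s.se_out[nz]
    b = wm(bx, by, seo)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx + rng.normal(0.0, sex)
        byi = by + rng.normal(0.0, seo)
        boots[i] = wm(bxi, byi, seo)
    se = float(np.nanstd(boots))
    scale_f = s.exposure_sd if per_sd else 1.0
    if se == 0.0:
        se = 1e-12
    return _from_log(
        "weighted_median",
        "per 1-SD" if per_sd else "per unit",
        "HR",
        b * scale_f,
        se * scale_f,
        int(nz.sum()),
        extras={"n_boot": n_boot},
    )


def quintiles_of_prediction(
    s1: StageOneFit, cohort: pd.DataFrame, model: CovariateModel | None = None
) -> QuintileResult:
    """Fifths of the genetically predicted exposure, analyzed exactly like
    the observational fifths (bottom fifth as reference)."""
    sub = cohort.set_index("sample_id").loc[s1.sample_index].reset_index()
    sub = sub.copy()
    sub["_prediction"] = s1.standardized if not s1.binary else s1.prediction
    return quintile_analysis(
        sub, "_prediction", model=model or DEFAULT_COVARIATE_MODELS["minimal"]
    )


def subgroup_mr(
    cohort: pd.DataFrame,
    grs: pd.Series,
    exposure: str,
    by: str = "sex",
    min_events: int = 50,
    model: CovariateModel = MR_MODEL,
):
    """Two-stage MR within strata of sex or 10-year age band.

    Stage one is refit within each stratum. Strata with fewer than
    ``min_events`` incident events are skipped with a log entry. Returns
    (list of (stratum label, MrEstimate), skipped labels)."""
    if by == "sex":
        labels = {f"sex={v}": cohort["sex"] == v for v in sorted(cohort["sex"].unique())}
    elif by == "age_band":
        band = (cohort["age"] // 10 * 10).astype(int)
        labels = {f"age_{v}s": band == v for v in sorted(band.unique())}
    else:
        raise ValueError("by must be 'sex' or 'age_band'")
    # the stratifier cannot also be an adjustment covariate
    cols = tuple(c for c in model.columns if c != ("sex" if by == "sex" else "age"))
    strat_model = CovariateModel(model.name + f"_by_{by}", cols, model.age_bands)
    out, skipped = [], []
    for label, mask in labels.items():
        sub = cohort.loc[mask.to_numpy()].reset_index(drop=True)
        n_ev = int(sub.loc[sub.get("prevalent", 0) == 0, "event"].sum())
        if n_ev < min_events or len(sub) == 0:
            logger.warning("stratum %s skipped: %d events < %d", label, n_ev, min_events)
            skipped.append(label)
            continue
        s1 = stage_one(sub, grs, exposure, model=strat_model)
        est = stage_two_cox(s1, sub, model=strat_model)
        out.append((label, est))
    return out, skipped


def run_mr(
    panel,
    cohort: pd.DataFrame,
    grs: pd.Series,
    exposure: str,
    estimators=("two_stage_cox", "two_stage_logistic", "ivw", "mr_egger", "weighted_median"),
    n_boot: int = 1000,
    seed: int = 0,
    model: CovariateModel = MR_MODEL,
):
    """Run the full MR battery for one exposure; returns
    (list of MrEstimate, StageOneFit, SnpSummary or None)."""
    s1 = stage_one(cohort, grs, exposure, model=model)
    results = []
    summary = None
    need_snp = {"ivw", "mr_egger", "weighted_median"} & set(estimators)
    for est in estimators:
        if est == "two_stage_cox":
            results.append(stage_two_cox(s1, cohort, model=model))
        elif est == "two_stage_logistic":
            results.append(stage_two_logistic(s1, cohort, model=model))
    if need_snp:
        sub = cohort.loc[cohort["sample_id"].isin(s1.sample_index)]
        summary = per_snp_associations(panel, sub, exposure, model=model)
        if "ivw" in estimators:
            results.append(ivw(summary))
        if "mr_egger" in estimators:
            results.append(mr_egger(summary))
        if "weighted_median" in estimators:
            results.append(weighted_median(summary, n_boot=n_boot, seed=seed))
    return results, s1, summary
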