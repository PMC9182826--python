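"""Observational Cox scan over exposures.

Per-exposure Cox proportional-hazards fits under config-declared covariate
models, hazard ratios rescaled to reporting units, a proportional-hazards
diagnostic per fit, multiplicity control by Bonferroni correction,
equal-frequency quintile (fifths) analysis with an inverse-variance-
weighted log-linear trend, and the reverse-causation sensitivity
exclusions (lipid-medication users; follow-up shorter than three years).

Prevalent cases are excluded before any Cox fit: follow-up is time from
baseline to the incident event or censoring, whichever comes first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engines

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureSpec",
    "QuintileResult",
    "CovariateModel",
    "DEFAULT_COVARIATE_MODELS",
    "bonferroni_threshold",
    "build_design",
    "run_exposure_scan",
    "quintile_analysis",
    "trend_fit",
    "sensitivity_exclusions",
]

AGE_BANDS = list(range(35, 75, 5))  # 5-year bands spanning recruitment ages


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure's scan configuration.

    ``unit`` is the reporting increment on the exposure's own scale (e.g.
    10 for "per 10 mmHg"); the scanned hazard ratio is exp(coef * unit).
    """

    name: str
    unit: float = 1.0
    unit_label: str = "per 1 unit"
    model: str = "full"
    lipid_adjust: bool = False
    binary: bool = False

    def __post_init__(self):
        if self.unit <= 0:
            raise ValueError("unit scaling must be positive")


@dataclass(frozen=True)
class CovariateModel:
    """Named adjustment set; ``age_bands`` expands age into 5-year
    ordered-category indicators rather than a linear term."""

    name: str
    columns: tuple[str, ...]
    age_bands: bool = True


DEFAULT_COVARIATE_MODELS = {
    "minimal": CovariateModel("minimal", ("sex", "age")),
    "full": CovariateModel(
        "full",
        (
            "sex",
            "age",
            "family_history",
            "education",
            "income",
            "townsend",
            "mets",
            "alcohol",
            "smoking_status",
            "sbp",
        ),
    ),
    "mr": CovariateModel(
        "mr",
        ("sex", "age") + tuple(f"pc{k}" for k in range(1, 11)) + ("chip",),
        age_bands=False,
    ),
}


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise corrected significance threshold alpha/k."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def _age_band_indicators(age: pd.Series) -> pd.DataFrame:
    band = pd.cut(age, bins=AGE_BANDS, right=False, labels=False, include_lowest=True)
    band = band.fillna(-1).astype(int)
    cats = sorted(b for b in band.unique() if b >= 0)
    out = {}
    for b in cats[1:]:  # lowest band is the reference
        lo = AGE_BANDS[b]
        out[f"age_{lo}_{lo + 4}"] = (band == b).astype(float)
    return pd.DataFrame(out, index=age.index)


def build_design(
    cohort: pd.DataFrame, model: CovariateModel, extra: dict[str, np.ndarray] | None = None
):
    """Assemble a Cox design matrix (no intercept) for an adjustment set.

    Categorical stand-ins (education, income, smoking_status) enter as
    indicator columns; age enters as 5-year band indicators when the model
    requests it. ``extra`` columns (the exposure / prediction / dosage of
    interest) are placed first.
    """
    pieces = []
    names = []
    if extra:
        for nm, col in extra.items():
            pieces.append(np.asarray(col, dtype=float)[:, None])
            names.append(nm)
    for col in model.columns:
        if col == "age" and model.age_bands:
            bands = _age_band_indicators(cohort["age"])
            pieces.append(bands.to_numpy(dtype=float))
            names.extend(bands.columns.tolist())
        elif col in ("education", "income", "smoking_status"):
            vals = cohort[col].astype(int)
            for lev in sorted(vals.unique())[1:]:
                pieces.append((vals == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{col}_{lev}")
        else:
            pieces.append(cohort[col].to_numpy(dtype=float)[:, None])
            names.append(col)
    X = np.hstack(pieces)
    return X, names


def _incident_subset(cohort: pd.DataFrame) -> pd.DataFrame:
    if "prevalent" in cohort.columns:
        return cohort.loc[cohort["prevalent"] == 0]
    return cohort


def run_exposure_scan(
    cohort: pd.DataFrame,
    exposure_specs,
    alpha: float = 0.05,
    models: dict[str, CovariateModel] | None = None,
    k_tests: int | None = None,
) -> pd.DataFrame:
    """One Cox fit per exposure under its covariate model.

    Returns a tidy table with per-unit hazard ratios, 95% CIs, Wald
    p-values, the proportional-hazards diagnostic p, and significance
    flags at ``alpha`` and at the Bonferroni-corrected threshold
    (``alpha / k_tests``, with ``k_tests`` defaulting to the number of
    exposures scanned). Absent or constant exposure columns are skipped
    with a logged reason.
    """
    models = models or DEFAULT_COVARIATE_MODELS
    specs = list(exposure_specs)
    k = k_tests if k_tests is not None else len(specs)
    thr = bonferroni_threshold(alpha, k)
    inc = _incident_subset(cohort)
    rows = []
    for spec in specs:
        if spec.name not in inc.columns:
            logger.warning("exposure %s absent from cohort; skipped", spec.name)
            continue
        sub = inc.loc[inc[spec.name].notna()]
        x = sub[spec.name].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            logger.warning("exposure %s is constant; skipped", spec.name)
            continue
        model = models[spec.model]
        cols = model.columns
        if spec.lipid_adjust and "lipid_med" in sub.columns:
            model = CovariateModel(model.name, cols + ("lipid_med",), model.age_bands)
        X, names = build_design(sub, model, extra={spec.name: x})
        fit = engines.fit_cox(
            sub["followup_years"].to_numpy(),
            sub["event"].to_numpy(),
            X,
            terms=names,
        )
        coef, se = fit[spec.name]
        ph = engines.ph_test(fit, sub["followup_years"], sub["event"], X)
        p = float(fit.pvalues[fit.terms.index(spec.name)])
        u = spec.unit
        rows.append(
            {
                "exposure": spec.name,
                "unit": spec.unit_label,
                "hr": float(np.exp(coef * u)),
                "ci_low": float(np.exp((coef - 1.959963984540054 * se) * u)),
                "ci_high": float(np.exp((coef + 1.959963984540054 * se) * u)),
                "p": p,
                "ph_p": ph[spec.name],
                "ph_ok": ph[spec.name] > 0.05,
                "n": fit.n,
                "events": fit.n_events,
                "sig_raw": p < alpha,
                "sig_bonferroni": p < thr,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QuintileResult:
    """Fifths analysis: per-group HR vs the bottom fifth, plus an
    inverse-variance-weighted log-linear trend."""

    exposure: str
    cut_points: np.ndarray
    groups: pd.DataFrame  # group, n, events, median, log_hr, se, hr, ci_low, ci_high
    reference: int = 0
    trend_slope: float = float("nan")
    trend_se: float = float("nan")


def _quintile_groups(x: np.ndarray, n_groups: int = 5):
    """Equal-frequency group assignment by rank (ties broken by order),
    guaranteeing group sizes equal to within one."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    g = np.empty(n, dtype=int)
    start = 0
    for k, s in enumerate(sizes):
        g[order[start : start + s]] = k
        start += s
    cuts = np.quantile(x, np.linspace(0, 1, n_groups + 1)[1:-1])
    return g, cuts


def quintile_analysis(
    cohort: pd.DataFrame,
    exposure: str,
    model: CovariateModel | None = None,
    n_groups: int = 5,
) -> QuintileResult:
    """Cox fit with fifth-group indicators, bottom fifth as reference."""
    model = model or DEFAULT_COVARIATE_MODELS["minimal"]
    inc = _incident_subset(cohort)
    sub = inc.loc[inc[exposure].notna()]
    x = sub[exposure].to_numpy(dtype=float)
    if len(np.unique(x)) < n_groups:
        raise ValueError(
            f"exposure {exposure!r} has fewer than {n_groups} distinct values"
        )
    g, cuts = _quintile_groups(x, n_groups)
    extra = {f"q{k}": (g == k).astype(float) for k in range(1, n_groups)}
    X, names = build_design(sub, model, extra=extra)
    fit = engines.fit_cox(
        sub["followup_years"].to_numpy(), sub["event"].to_numpy(), X, terms=names
    )
    ev = sub["event"].to_numpy()
    recs = []
    for k in range(n_groups):
        in_g = g == k
        if k == 0:
            log_hr, se = 0.0, np.nan
        else:
            log_hr, se = fit[f"q{k}"]
        recs.append(
            {
                "group": k,
                "n": int(in_g.sum()),
                "events": int(ev[in_g].sum()),
                "median": float(np.median(x[in_g])),
                "log_hr": float(log_hr),
                "se": float(se) if np.isfinite(se) else np.nan,
                "hr": float(np.exp(log_hr)),
                "ci_low": float(np.exp(log_hr - 1.959963984540054 * se))
                if np.isfinite(se)
                else np.nan,
                "ci_high": float(np.exp(log_hr + 1.959963984540054 * se))
                if np.isfinite(se)
                else np.nan,
            }
        )
    result = QuintileResult(
        exposure=exposure, cut_points=cuts, groups=pd.DataFrame(recs)
    )
    slope, se = trend_fit(result)
    result.trend_slope = slope
    result.trend_se = se
    return result


def trend_fit(quintile_result: QuintileResult):
    """Weighted least squares of group log HR on group median exposure.

    Weights are inverse variances of the log HRs. The reference group sits
    at log HR 0; its sampling variance is zero by construction, so it
    enters with the largest finite weight among the other groups (an
    infinite weight would pin the line; the cap keeps the fit defined).
    """
    gdf = quintile_result.groups
    nonref = gdf.loc[gdf["group"] != quintile_result.reference]
    se = nonref["se"].to_numpy(dtype=float)
    finite = np.isfinite(se) & (se > 0)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-reference groups with finite SEs")
    w_ref = (1.0 / se[finite] ** 2).max()
    xs = gdf["median"].to_numpy(dtype=float)
    ys = gdf["log_hr"].to_numpy(dtype=float)
    ws = np.empty(len(gdf))
    for i, (_, row) in enumerate(gdf.iterrows()):
        if row["group"] == quintile_result.reference:
            ws[i] = w_ref
        elif np.isfinite(row["se"]) and row["se"] > 0:
            ws[i] = 1.0 / row["se"] ** 2
        else:
            ws[i] = 0.0
    if np.all(ws == 0):
        raise ValueError("all trend weights are zero or undefined")
    W = ws
    xbar = np.average(xs, weights=W)
    ybar = np.average(ys, weights=W)
    sxx = float(np.sum(W * (xs - xbar) ** 2))
    slope = float(np.sum(W * (xs - xbar) * (ys - ybar)) / sxx)
    se_slope = float(np.sqrt(1.0 / sxx))
    return slope, se_slope


SENSITIVITY_RULES = ("drop_lipid_med_users", "drop_followup_lt_3y", "both")


def sensitivity_exclusions(cohort: pd.DataFrame, rule: str):
    """Reverse-causation sensitivity subsets.

    ``drop_lipid_med_users`` removes baseline lipid-lowering-medication
    users; ``drop_followup_lt_3y`` removes follow-up strictly shorter than
    three years (exactly 3.0 years is retained). Returns (subset, log)."""
    if rule not in SENSITIVITY_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {SENSITIVITY_RULES}")
    out = cohort
    log = {}
    if rule in ("drop_lipid_med_users", "both"):
        before = len(out)
        out = out.loc[out["lipid_med"] == 0]
        log["removed_lipid_med_users"] = before - len(out)
    if rule in ("drop_followup_lt_3y", "both"):
        before = len(out)
        out = out.loc[out["followup_years"] >= 3.0]
        log["removed_followup_lt_3y"] = before - len(out)
    if out.empty:
        raise ValueError("sensitivity exclusion removed every participant")
    return out.copy(), log
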