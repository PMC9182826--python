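"""MR pipeline: stage-one construction, two-stage estimation and its
invariances, per-SNP summaries, and the pleiotropy-robust estimators."""

import numpy as np
import pandas as pd
import pytest

from mrsurv import grs as grs_mod
from mrsurv import mr
from mrsurv.observational import CovariateModel
from mrsurv.simulate import SimulationScenario, simulate_cohort

NO_COVARIATES = CovariateModel("none", ())


@pytest.fixture(scope="module")
def demo_grs(demo_sim):
    return grs_mod.build_grs(demo_sim.panel, demo_sim.weights)


# ---------------------------------------------------------------------------
# stage one
# ---------------------------------------------------------------------------


def test_standardized_prediction_moments(demo_sim, demo_grs):
    s1 = mr.stage_one(demo_sim.cohort, demo_grs.scores, "exposure_sim")
    assert abs(s1.standardized.mean()) < 1e-10
    assert abs(s1.standardized.std() - 1.0) < 1e-10
    assert s1.f_stat >= 0


def test_null_instruments_give_small_f(null_sim):
    rng = np.random.default_rng(0)
    noise_grs = pd.Series(
        rng.standard_normal(len(null_sim.cohort)),
        index=pd.Index(null_sim.cohort["sample_id"], name="sample_id"),
    )
    s1 = mr.stage_one(null_sim.cohort, noise_grs, "exposure_sim")
    assert s1.r2_grs < 0.002
    assert s1.f_stat < 8
    assert s1.weak


def test_f_statistic_matches_single_instrument_formula(demo_sim, demo_grs):
    """With no covariates, F for the GRS equals (n-2) R^2 / (1 - R^2)."""
    s1 = mr.stage_one(demo_sim.cohort, demo_grs.scores, "exposure_sim", model=NO_COVARIATES)
    n = s1.n
    r2 = s1.fit.r_squared
    oracle = (n - 2) * r2 / (1 - r2)
    assert s1.f_stat == pytest.approx(oracle, rel=1e-9)
    assert s1.f_stat > 10  # strong instrument in this scenario


# ---------------------------------------------------------------------------
# two-stage estimation
# ---------------------------------------------------------------------------


def test_grs_rescaling_leaves_two_stage_hr_unchanged(demo_sim, demo_grs):
    s1a = mr.stage_one(demo_sim.cohort, demo_grs.scores, "exposure_sim")
    s1b = mr.stage_one(demo_sim.cohort, demo_grs.scores * 7.3, "exposure_sim")
    ea = mr.stage_two_cox(s1a, demo_sim.cohort)
    eb = mr.stage_two_cox(s1b, demo_sim.cohort)
    assert ea.estimate == pytest.approx(eb.estimate, rel=1e-9)
    assert ea.log_se == pytest.approx(eb.log_se, rel=1e-9)


def test_single_snp_two_stage_equals_wald_ratio(demo_sim):
    """GRS built from one SNP: the two-stage per-unit log HR must equal
    beta_out / beta_exp computed from the same per-SNP regressions."""
    sid = demo_sim.panel.snp_ids[0]
    w1 = demo_sim.weights.iloc[[0]]
    grs1 = grs_mod.compute_grs(demo_sim.panel.subset_snps([sid]), w1)
    s1 = mr.stage_one(demo_sim.cohort, grs1.scores, "exposure_sim")
    est = mr.stage_two_cox(s1, demo_sim.cohort)
    per_unit = est.log_estimate / s1.exposure_sd
    summ = mr.per_snp_associations(
        demo_sim.panel, demo_sim.cohort, "exposure_sim", snp_ids=list(demo_sim.panel.snp_ids[:3])
    )
    j = summ.snp_ids.index(sid)
    wald = summ.beta_out[j] / summ.beta_exp[j]
    assert per_unit == pytest.approx(wald, rel=1e-5)


def test_two_stage_recovers_theta_under_confounding():
    """Small replicate check of unbiasedness: mean log HR within 3
    Monte-Carlo SEs of theta (the confounder is active on both sides)."""
    theta = float(np.log(1.5))
    logs = []
    for seed in range(12):
        sc = SimulationScenario(
            n_samples=8_000,
            n_snps=20,
            instrument_r2=0.1,
            causal_log_hr=theta,
            confounder_effect_exposure=0.4,
            confounder_log_hr=0.4,
            baseline_hazard=0.02,
            seed=100 + seed,
        )
        sim = simulate_cohort(sc)
        g = grs_mod.build_grs(sim.panel, sim.weights)
        s1 = mr.stage_one(sim.cohort, g.scores, "exposure_sim")
        logs.append(mr.stage_two_cox(s1, sim.cohort).log_estimate)
    logs = np.array(logs)
    mc_se = logs.std(ddof=1) / np.sqrt(len(logs))
    assert abs(logs.mean() - theta) < 3 * mc_se + 0.02


def test_logistic_or_close_to_cox_hr_for_rare_outcome():
    sc = SimulationScenario(
        n_samples=20_000,
        n_snps=20,
        instrument_r2=0.1,
        causal_log_hr=float(np.log(1.5)),
        baseline_hazard=0.003,  # rare outcome: OR ~ HR
        seed=55,
    )
    sim = simulate_cohort(sc)
    g = grs_mod.build_grs(sim.panel, sim.weights)
    s1 = mr.stage_one(sim.cohort, g.scores, "exposure_sim")
    hr = mr.stage_two_cox(s1, sim.cohort)
    or_ = mr.stage_two_logistic(s1, sim.cohort)
    assert or_.log_estimate == pytest.approx(
        hr.log_estimate, abs=1.0 * np.hypot(hr.log_se, or_.log_se)
    )


def test_all_prevalent_cases_break_cox_but_not_logistic(demo_sim, demo_grs):
    cohort = demo_sim.cohort.copy()
    cohort.loc[cohort["event"] == 1, "prevalent"] = 1
    cohort["event"] = 0
    cohort["prevalent"] = cohort["prevalent"].astype(int)
    s1 = mr.stage_one(cohort, demo_grs.scores, "exposure_sim")
    est = mr.stage_two_logistic(s1, cohort)
    assert np.isfinite(est.estimate)
    with pytest.raises(ValueError, match="no events"):
        mr.stage_two_cox(s1, cohort)


def test_binary_exposure_reports_per_category():
    sc = SimulationScenario(
        n_samples=15_000,
        n_snps=20,
        instrument_r2=0.1,
        causal_log_hr=float(np.log(1.6)),
        baseline_hazard=0.02,
        binary_exposure=True,
        binary_prevalence=0.3,
        seed=77,
    )
    sim = simulate_cohort(sc)
    g = grs_mod.build_grs(sim.panel, sim.weights)
    s1 = mr.stage_one(sim.cohort, g.scores, "exposure_sim")
    assert s1.binary
    est = mr.stage_two_cox(s1, sim.cohort)
    assert est.scale == "per category"
    assert est.log_estimate > 0  # correct direction for a harmful exposure


# ---------------------------------------------------------------------------
# per-SNP summaries
# ---------------------------------------------------------------------------


def test_per_snp_exposure_betas_recover_generator_gammas(demo_sim):
    summ = mr.per_snp_associations(demo_sim.panel, demo_sim.cohort, "exposure_sim")
    gamma = dict(zip(demo_sim.panel.snp_ids, demo_sim.truth.gamma))
    z = [
        (b - gamma[sid]) / se
        for sid, b, se in zip(summ.snp_ids, summ.beta_exp, summ.se_exp)
    ]
    assert np.mean(np.abs(z) < 4) == 1.0


def test_per_snp_outcome_betas_null_centred(null_sim):
    summ = mr.per_snp_associations(null_sim.panel, null_sim.cohort, "exposure_sim")
    z = summ.beta_out / summ.se_out
    assert abs(np.mean(z)) < 1.0
    assert np.mean(np.abs(z) < 3) >= 0.9


def test_fewer_than_three_snps_raises(demo_sim):
    with pytest.raises(ValueError, match="at least 3"):
        mr.per_snp_associations(
            demo_sim.panel.subset_snps(list(demo_sim.panel.snp_ids[:2])),
            demo_sim.cohort,
            "exposure_sim",
        )


# ---------------------------------------------------------------------------
# sensitivity estimators on constructed summaries
# ---------------------------------------------------------------------------


def summary(beta_exp, beta_out, se_exp=None, se_out=None):
    k = len(beta_exp)
    return mr.SnpSummary(
        snp_ids=[f"rs{j}" for j in range(k)],
        beta_exp=np.asarray(beta_exp, dtype=float),
        se_exp=np.asarray(se_exp if se_exp is not None else [0.01] * k, dtype=float),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out if se_out is not None else [0.05] * k, dtype=float),
        exposure_sd=1.0,
    )


def test_egger_exact_line_recovers_slope_and_intercept():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    alpha0, theta = 0.03, 0.5
    s = summary(bx, alpha0 + theta * bx)
    est = mr.mr_egger(s)
    assert est.log_estimate == pytest.approx(theta, abs=1e-10)
    assert est.egger_intercept == pytest.approx(alpha0, abs=1e-10)


def test_egger_degenerate_spread_raises():
    s = summary([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="spread"):
        mr.mr_egger(s)


def test_egger_orients_exposure_betas_positive():
    bx = np.array([0.1, -0.2, 0.3])
    theta = 0.4
    s = summary(bx, theta * bx)
    est = mr.mr_egger(s)
    assert est.log_estimate == pytest.approx(theta, abs=1e-10)
    assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)


def test_ivw_exact_line_and_wald_reduction():
    bx = np.array([0.1, 0.2, 0.4])
    theta = 0.25
    est = mr.ivw(summary(bx, theta * bx))
    assert est.log_estimate == pytest.approx(theta, abs=1e-12)
    # identical ratios: IVW equals the common Wald ratio
    est2 = mr.ivw(summary([0.2, 0.2], [0.1, 0.1]))
    assert est2.log_estimate == pytest.approx(0.5, abs=1e-12)


def test_weighted_median_unweighted_middle_ratio():
    # equal weights (equal beta_exp, equal se_out): plain median of ratios
    bx = np.array([1.0, 1.0, 1.0])
    by = np.array([0.1, 0.2, 0.6])
    est = mr.weighted_median(summary(bx, by), n_boot=200, seed=0)
    assert est.log_estimate == pytest.approx(0.2, abs=1e-9)


def test_weighted_median_degenerate_identical_ratios_tiny_se():
    bx = np.array([0.5, 0.4, 0.3])
    theta = 0.3
    s = summary(bx, theta * bx, se_exp=[1e-8] * 3, se_out=[1e-8] * 3)
    est = mr.weighted_median(s, n_boot=100, seed=0)
    assert est.log_estimate == pytest.approx(theta, abs=1e-6)
    assert est.log_se < 1e-6


def test_weighted_median_drops_zero_beta_snps():
    s = summary([0.0, 0.2, 0.3], [0.1, 0.1, 0.1])
    with pytest.raises(ValueError, match="fewer than 3"):
        mr.weighted_median(s, n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# quintiles of prediction and subgroups
# ---------------------------------------------------------------------------


def test_prediction_quintiles_monotone_under_positive_effect(demo_sim, demo_grs):
    s1 = mr.stage_one(demo_sim.cohort, demo_grs.scores, "exposure_sim")
    res = mr.quintiles_of_prediction(s1, demo_sim.cohort)
    sizes = res.groups["n"].to_numpy()
    assert sizes.max() - sizes.min() <= 1
    assert res.groups["hr"].iloc[-1] > 1.0
    assert res.trend_slope > 0


def test_subgroup_homogeneous_theta_agrees_across_sexes(demo_sim, demo_grs):
    ests, skipped = mr.subgroup_mr(
        demo_sim.cohort, demo_grs.scores, "exposure_sim", by="sex"
    )
    assert len(ests) == 2 and not skipped
    (l0, e0), (l1, e1) = ests
    # same generative effect in both sexes: estimates within joint MC error
    diff_se = float(np.hypot(e0.log_se, e1.log_se))
    assert abs(e0.log_estimate - e1.log_estimate) < 3 * diff_se


def test_subgroup_sex_specific_theta_separates():
    sims = []
    for sex, theta in ((0, 0.0), (1, float(np.log(2.2)))):
        sc = SimulationScenario(
            n_samples=6_000,
            n_snps=15,
            instrument_r2=0.15,
            causal_log_hr=theta,
            baseline_hazard=0.03,
            seed=300,  # same seed: same SNP panel structure per stratum
        )
        sims.append((sex, simulate_cohort(sc)))
    panel0, panel1 = sims[0][1].panel, sims[1][1].panel
    dosages = np.vstack([panel0.dosages, panel1.dosages])
    sample_ids = [f"A{i}" for i in range(panel0.n_samples)] + [
        f"B{i}" for i in range(panel1.n_samples)
    ]
    panel = grs_mod.GenotypePanel(
        dosages=dosages, sample_ids=sample_ids, snp_ids=panel0.snp_ids
    )
    frames = []
    for (sex, sim), prefix in zip(sims, ("A", "B")):
        df = sim.cohort.copy()
        df["sample_id"] = [f"{prefix}{i}" for i in range(len(df))]
        df["sex"] = sex
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    g = grs_mod.build_grs(panel, sims[0][1].weights)
    ests, _ = mr.subgroup_mr(cohort, g.scores, "exposure_sim", by="sex")
    by_label = {label: e for label, e in ests}
    assert by_label["sex=1"].log_estimate > by_label["sex=0"].log_estimate + 0.3


def test_subgroup_small_stratum_skipped(demo_sim, demo_grs):
    cohort = demo_sim.cohort.copy()
    # push nearly everyone into one sex so the other has too few events
    few = cohort.index[:40]
    cohort["sex"] = 0
    cohort.loc[few, "sex"] = 1
    ests, skipped = mr.subgroup_mr(cohort, demo_grs.scores, "exposure_sim", by="sex")
    assert "sex=1" in skipped
    assert [label for label, _ in ests] == ["sex=0"]
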