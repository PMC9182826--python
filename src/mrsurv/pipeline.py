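"""Config-driven orchestration: simulate -> GRS -> observational scan ->
MR battery, with deterministic seeding, run logs, and flat TSV outputs.

A run is described by one YAML config with either the paths of the three
study inputs or a simulation scenario block (never both), an exposure
registry, the estimator list, and multiplicity settings. Everything the
pipeline writes is machine-readable (TSV/JSON); the rendered forest table
repeats numbers that also exist in the estimates TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, grs as grs_mod, io as io_mod, mr as mr_mod
from . import observational as obs_mod
from .simulate import SimulationScenario, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_forest_table", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    inputs: dict | None = None  # {"weights":..., "dosages":..., "cohort":...}
    scenario: SimulationScenario | None = None
    exposures: list[obs_mod.ExposureSpec] = field(default_factory=list)
    estimators: tuple[str, ...] = (
        "two_stage_cox",
        "two_stage_logistic",
        "ivw",
        "mr_egger",
        "weighted_median",
    )
    alpha: float = 0.05
    k_bonferroni: int | None = None
    p_threshold: float = grs_mod.GENOME_WIDE_P
    r2_threshold: float = grs_mod.LD_R2_THRESHOLD
    n_boot: int = 1000
    seed: int | None = None
    outdir: str = "mrsurv_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        problems = []
        inputs = d.get("inputs")
        scen_block = d.get("scenario")
        if (inputs is None) == (scen_block is None):
            problems.append("exactly one of 'inputs' and 'scenario' must be present")
        scenario = None
        if scen_block is not None:
            if d.get("seed") is None and "seed" not in scen_block:
                problems.append("seed is mandatory when simulating")
            try:
                scenario = SimulationScenario(**scen_block)
                if d.get("seed") is not None:
                    scenario = scenario.with_(seed=int(d["seed"]))
                scenario.validate()
            except (TypeError, ValueError) as exc:
                problems.append(f"invalid scenario: {exc}")
        if inputs is not None:
            for key in ("weights", "dosages", "cohort"):
                if key not in inputs:
                    problems.append(f"inputs block missing path {key!r}")
        exposures = []
        for e in d.get("exposures", []):
            try:
                exposures.append(obs_mod.ExposureSpec(**e))
            except (TypeError, ValueError) as exc:
                problems.append(f"invalid exposure spec {e}: {exc}")
        if not exposures and scenario is not None:
            exposures = [obs_mod.ExposureSpec(name="exposure_sim", model="full")]
        alpha = float(d.get("alpha", 0.05))
        if not (0 < alpha < 1):
            problems.append("alpha must be in (0,1)")
        if problems:
            raise ConfigError("; ".join(problems))
        return cls(
            inputs=inputs,
            scenario=scenario,
            exposures=exposures,
            estimators=tuple(d.get("estimators", cls.estimators)),
            alpha=alpha,
            k_bonferroni=d.get("k_bonferroni"),
            p_threshold=float(d.get("p_threshold", grs_mod.GENOME_WIDE_P)),
            r2_threshold=float(d.get("r2_threshold", grs_mod.LD_R2_THRESHOLD)),
            n_boot=int(d.get("n_boot", 1000)),
            seed=d.get("seed"),
            outdir=d.get("outdir", "mrsurv_out"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def render_forest_table(estimates: pd.DataFrame, alpha=0.05, k=None) -> str:
    """Aligned text forest-style table: one line per exposure x estimator
    with 'HR (lo-hi)' and significance markers (* at alpha, ** at the
    Bonferroni-corrected alpha)."""
    if estimates.empty:
        raise ValueError("no estimates to render")
    for col in ("estimate", "ci_low", "ci_high"):
        if estimates[col].isna().any():
            raise ValueError(f"cannot render: missing values in {col!r}")
    k = k or estimates["exposure"].nunique()
    thr = obs_mod.bonferroni_threshold(alpha, k)
    lines = []
    header = f"{'exposure':<16}{'estimator':<20}{'scale':<14}{'estimate (95% CI)':<26}{'p':<10}sig"
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in estimates.iterrows():
        sig = "**" if r["p"] < thr else ("*" if r["p"] < alpha else "")
        ci = f"{r['estimate']:.2f} ({r['ci_low']:.2f}–{r['ci_high']:.2f})"
        lines.append(
            f"{str(r['exposure']):<16}{str(r['estimator']):<20}"
            f"{str(r['scale']):<14}{ci:<26}{r['p']:<10.3g}{sig}"
        )
    return "\n".join(lines)


def run_pipeline(config: RunConfig, outdir=None, seed=None) -> dict:
    """Execute the configured run end to end.

    Writes under the output directory: the simulated fixture (if any),
    grs.tsv + grs_provenance.json, observational.tsv, quintiles TSVs,
    mr_estimates.tsv, forest.txt, run.log (human-readable) and
    events.jsonl (machine-readable). Returns a manifest of paths."""
    outdir = outdir or config.outdir
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
        if config.scenario is not None:
            config = dataclasses.replace(
                config, scenario=config.scenario.with_(seed=seed)
            )
    os.makedirs(outdir, exist_ok=True)
    events_path = os.path.join(outdir, "events.jsonl")
    log_path = os.path.join(outdir, "run.log")
    events = []
    loglines = []

    def note(event, **kw):
        events.append({"event": event, **kw})
        loglines.append(f"{event}: " + ", ".join(f"{k}={_fmt(v)}" for k, v in kw.items()))

    note("start", version=__version__, seed=config.seed)

    if config.scenario is not None:
        sim = simulate_cohort(config.scenario)
        panel, cohort, weights = sim.panel, sim.cohort, sim.weights
        fixture = io_mod.write_fixture(panel, cohort, weights, os.path.join(outdir, "fixture"))
        note("simulated", n_samples=panel.n_samples, n_snps=panel.n_snps, **{
            k: str(v) for k, v in fixture.items()
        })
    else:
        panel = io_mod.read_dosages(config.inputs["dosages"])
        cohort = io_mod.read_cohort(config.inputs["cohort"])
        weights = io_mod.read_weights(config.inputs["weights"])
        note("loaded", n_samples=panel.n_samples, n_snps=panel.n_snps)

    # ----- GRS -----
    grs_vec = grs_mod.build_grs(
        panel, weights, p_threshold=config.p_threshold, r2_threshold=config.r2_threshold
    )
    grs_path = os.path.join(outdir, "grs.tsv")
    _write_tsv(grs_vec.scores.rename("grs").reset_index(), grs_path)
    prov = {
        "retained_snps": grs_vec.snp_ids,
        "betas": [float(b) for b in grs_vec.betas],
        **(grs_vec.log.to_dict() if grs_vec.log else {}),
    }
    prov_path = os.path.join(outdir, "grs_provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    note("grs_built", **(grs_vec.log.to_dict() if grs_vec.log else {}))

    # ----- observational scan -----
    k = config.k_bonferroni or len(config.exposures)
    scan = obs_mod.run_exposure_scan(
        cohort, config.exposures, alpha=config.alpha, k_tests=k
    )
    obs_path = os.path.join(outdir, "observational.tsv")
    _write_tsv(scan, obs_path)
    note(
        "observational_scan",
        n_exposures=len(scan),
        bonferroni_threshold=obs_mod.bonferroni_threshold(config.alpha, k),
    )

    # ----- quintiles + MR per exposure -----
    mr_rows = []
    quintile_frames = []
    seed0 = int(config.seed or 0)
    for spec in config.exposures:
        if spec.name not in cohort.columns:
            continue
        try:
            q_obs = obs_mod.quintile_analysis(cohort, spec.name)
            qdf = q_obs.groups.assign(
                exposure=spec.name, kind="observed",
                trend_slope=q_obs.trend_slope, trend_se=q_obs.trend_se,
            )
            quintile_frames.append(qdf)
        except ValueError as exc:
            note("quintiles_skipped", exposure=spec.name, reason=str(exc))
        ests, s1_fit, _ = mr_mod.run_mr(
            panel,
            cohort,
            grs_vec.scores,
            spec.name,
            estimators=config.estimators,
            n_boot=config.n_boot,
            seed=seed0,
        )
        for est in ests:
            mr_rows.append({"exposure": spec.name, **est.as_row()})
        q_pred = mr_mod.quintiles_of_prediction(s1_fit, cohort)
        quintile_frames.append(
            q_pred.groups.assign(
                exposure=spec.name, kind="predicted",
                trend_slope=q_pred.trend_slope, trend_se=q_pred.trend_se,
            )
        )
        note("mr_done", exposure=spec.name, F=s1_fit.f_stat, weak=s1_fit.weak)

    mr_df = pd.DataFrame(mr_rows)
    mr_path = os.path.join(outdir, "mr_estimates.tsv")
    _write_tsv(mr_df, mr_path)
    qpath = os.path.join(outdir, "quintiles.tsv")
    _write_tsv(pd.concat(quintile_frames, ignore_index=True), qpath)

    forest = render_forest_table(mr_df, alpha=config.alpha, k=k)
    forest_path = os.path.join(outdir, "forest.txt")
    with open(forest_path, "w") as fh:
        fh.write(forest + "\n")
    note("done", outdir=outdir)

    with open(events_path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
    with open(log_path, "w") as fh:
        fh.write("\n".join(loglines) + "\n")
    return {
        "grs": grs_path,
        "grs_provenance": prov_path,
        "observational": obs_path,
        "mr_estimates": mr_path,
        "quintiles": qpath,
        "forest": forest_path,
        "events": events_path,
        "log": log_path,
    }
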