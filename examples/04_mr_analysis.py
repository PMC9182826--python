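"""Full one-sample MR battery on a confounded null and on a real effect.

For each cohort: stage-one F (instrument strength), two-stage Cox HR per
1-SD exposure, logistic OR robustness check, and the pleiotropy-robust
IVW / MR-Egger / weighted-median estimators with the Egger intercept
pleiotropy diagnostic.
"""

import numpy as np

from mrsurv import SimulationScenario, simulate_cohort
from mrsurv.grs import build_grs
from mrsurv.mr import run_mr

for label, theta in (("confounded null (true HR 1.0)", 0.0),
                     ("real effect (true HR 1.4)", float(np.log(1.4)))):
    sim = simulate_cohort(
        SimulationScenario(
            n_samples=12_000,
            n_snps=20,
            instrument_r2=0.08,
            causal_log_hr=theta,
            confounder_effect_exposure=0.5,
            confounder_log_hr=0.5,
            baseline_hazard=0.015,
            seed=37,
        )
    )
    grs = build_grs(sim.panel, sim.weights)
    estimates, stage1, summary = run_mr(
        sim.panel, sim.cohort, grs.scores, "exposure_sim", seed=1
    )
    print(f"\n=== {label} ===")
    print(f"stage-one F = {stage1.f_stat:.0f} "
          f"(R^2 from GRS = {stage1.r2_grs:.3f}; weak instrument: {stage1.weak})")
    for e in estimates:
        extra = ""
        if e.egger_intercept is not None:
            extra = (f"  intercept {e.egger_intercept:+.4f} "
                     f"(p = {e.egger_intercept_p:.2f})")
        print(f"{e.estimator:<20}{e.ratio_measure} {e.estimate:5.2f} "
              f"({e.ci_low:.2f}-{e.ci_high:.2f}) {e.scale}{extra}")

# In the null cohort every genetic estimator's CI covers 1 even though
# the observational scan (example 03) is strongly positive; in the effect
# cohort all estimators centre near HR 1.4 and the Egger intercept stays
# consistent with no directional pleiotropy.
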