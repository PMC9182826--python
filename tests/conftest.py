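import numpy as np
import pytest

from mrsurv.simulate import SimulationScenario, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_sim():
    """Moderate cohort with a real causal effect, reused across tests."""
    scenario = SimulationScenario(
        n_samples=6_000,
        n_snps=20,
        instrument_r2=0.1,
        causal_log_hr=float(np.log(1.5)),
        confounder_effect_exposure=0.4,
        confounder_log_hr=0.4,
        baseline_hazard=0.02,
        prevalent_rate=0.005,
        seed=42,
    )
    return simulate_cohort(scenario)


@pytest.fixture(scope="session")
def null_sim():
    """No causal effect, no pleiotropy, but exposure-outcome confounding."""
    scenario = SimulationScenario(
        n_samples=6_000,
        n_snps=20,
        instrument_r2=0.1,
        causal_log_hr=0.0,
        confounder_effect_exposure=0.5,
        confounder_log_hr=0.5,
        baseline_hazard=0.02,
        seed=99,
    )
    return simulate_cohort(scenario)
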