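import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hinhcost import GeneratorConfig, load_parameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def baseline():
    """Baseline parameter set and distribution specs of the published analysis."""
    return load_parameters()


@pytest.fixture(scope="session")
def baseline_params(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def baseline_specs(baseline):
    return baseline[1]


@pytest.fixture()
def null_config():
    """Generator with all effect ratios 1 and simple marginals."""
    return GeneratorConfig(
        months_per_period=3,
        beds_per_catchment=1000.0,
        baseline_rates={"presentations": 60.0, "admissions": 30.0},
        hospital_rate_ratio=1.0,
        year_rate_ratio=1.0,
        intervention_rate_ratio=1.0,
        baseline_los_means={"ed": 10.0, "inpatient": 80.0},
        hospital_los_ratio=1.0,
        year_los_ratio=1.0,
        intervention_los_ratio=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_data():
    """One coherent draw at published-default effect sizes, ~5,000 episodes."""
    from hinhcost import generate

    config = GeneratorConfig(beds_per_catchment=6300.0, seed=11)
    episodes, monthly = generate(config)
    return config, episodes, monthly


def rng(seed=0):
    return np.random.default_rng(seed)
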