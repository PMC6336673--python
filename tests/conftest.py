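import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from apadapt.cohort import ScenarioConfig
from apadapt.evaluate import run_scenario
from apadapt.metabolism import generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: study seed used throughout the suite; matches the package-wide default
STUDY_SEED = 0


@pytest.fixture(scope="session")
def cohort10():
    return generate_cohort(10, STUDY_SEED)


@pytest.fixture(scope="session")
def patient(cohort10):
    return cohort10[0]


@pytest.fixture(scope="session")
def scenario2_study(cohort10):
    """Full 24-week Scenario II (doubled BR and CR) adaptation study."""
    config = ScenarioConfig.preset("II", seed=STUDY_SEED, weeks=24)
    return config, run_scenario(cohort10, config)


@pytest.fixture(scope="session")
def scenario1_study(cohort10):
    """Full 24-week Scenario I (halved BR, doubled CR) adaptation study."""
    config = ScenarioConfig.preset("I", seed=STUDY_SEED, weeks=24)
    return config, run_scenario(cohort10, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
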