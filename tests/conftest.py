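import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msceoac import HazardEvaluator, demo_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return demo_config()


@pytest.fixture(scope="session")
def evaluator(cfg):
    return HazardEvaluator(cfg)


@pytest.fixture(scope="session")
def male_curve(evaluator):
    return evaluator.curve("M", 1950)


@pytest.fixture(scope="session")
def truth():
    """Ground-truth parameter values of the demo configuration."""
    c = demo_config()
    return {
        "nu0_M": c.nu0("M"),
        "nu0_F": c.nu0("F"),
        "mu2": c.biology().mu2,
        "cohort_1930": c.cohort_multipliers[1930],
        "cohort_1940": c.cohort_multipliers[1940],
    }
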