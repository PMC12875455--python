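import logging

import pytest
from hypothesis import HealthCheck, settings

from leafpart import PartitionParams, TrialDesign, generate_trial

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the generator logs every skipped plant; keep test output readable
logging.getLogger("leafpart.synthetic_data").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params():
    return PartitionParams.default()


@pytest.fixture(scope="session")
def small_design():
    """One treatment cell, two plants per date: fast end-to-end runs."""
    return TrialDesign(
        cultivars=("V1",),
        n_levels=("N1",),
        densities=("D2",),
        plants_per_treatment=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_trial():
    return generate_trial(TrialDesign(), noise_sd=0.0)
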