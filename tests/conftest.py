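import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viralshunt.dynamics import DEFAULT_PARAMS
from viralshunt.inference import FitConfig, run_three_stage_fit
from viralshunt.synthetic import BatchNoiseModel, generate_batch_suite

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def noiseless_suite():
    """Noise-free replicate curves for all six preset mixes."""
    return generate_batch_suite(DEFAULT_PARAMS, BatchNoiseModel(od_cv=0.0), seed=1)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_suite):
    """Three-stage fit of the noise-free suite (shared across tests)."""
    return run_three_stage_fit(noiseless_suite, FitConfig())


@pytest.fixture(scope="session")
def noisy_suite():
    """Default-noise (5% CV, 4 replicates) curves for all preset mixes."""
    return generate_batch_suite(DEFAULT_PARAMS, BatchNoiseModel(), seed=7)
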