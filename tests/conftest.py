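import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speechpac.synthetic import (
    SyntheticCohortConfig,
    generate_envelope,
    generate_neural,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config() -> SyntheticCohortConfig:
    """Standard study conditions: 60 s per subject at 200 Hz, 5.5 Hz
    syllabic rate, 33 Hz gamma, coupling depth 0.7, SNR 1."""
    return SyntheticCohortConfig(seed=101)


@pytest.fixture(scope="session")
def coupled_pair(base_config):
    """One strongly coupled envelope/neural pair (normal condition)."""
    env = generate_envelope(base_config, "normal", np.random.default_rng(11))
    neural = generate_neural(env, base_config, np.random.default_rng(12))
    return env, neural
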