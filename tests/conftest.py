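import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cryosip import SimulationConfig, simulate_experiment  # noqa: E402


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment shared across tests."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_sim():
    """Deterministic labelling with a constant DIC pool label."""
    cfg = SimulationConfig(seed=5, noise_free=True,
                           dic_excess_half_life_h=None)
    return simulate_experiment(cfg)
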