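import numpy as np
import pytest

from huvsd import PopulationParams, SimulationConfig, generate


@pytest.fixture(scope="session")
def recovery_pop() -> PopulationParams:
    """The reference population used across the simulation studies."""
    return PopulationParams(mu_d=2.0, mu_c=-0.5, sigma_d=0.6, sigma_c=0.4, sigma_s=1.5)


@pytest.fixture(scope="session")
def small_dataset(recovery_pop):
    """A small dataset for fast sampler smoke tests."""
    cfg = SimulationConfig(
        pop=recovery_pop,
        n_participants=30,
        signal_trials=60,
        noise_trials=60,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240528)
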