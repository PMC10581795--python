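import numpy as np
import pytest

from fluolut import OpticalMedium, SimulationConfig, simulate_impulse


@pytest.fixture(scope="session")
def diffusive_medium():
    """A comfortably diffusive medium (mu_s' >> mu_a)."""
    return OpticalMedium(mu_a=0.01, mu_s_prime=1.0, n=1.37)


@pytest.fixture(scope="session")
def diffusive_impulse(diffusive_medium):
    """Moderate-statistics impulse response reused across tests."""
    cfg = SimulationConfig(n_photons=150_000, seed=42)
    return simulate_impulse(diffusive_medium, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
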