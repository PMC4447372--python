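import numpy as np
import pytest

from spinefcs import (
    SimulationConfig,
    SpeciesSpec,
    autocorrelate,
    simulate_trace,
)


@pytest.fixture(scope="session")
def single_species_trace():
    """30-s one-species trace (N = 5, tau_D = 4.1 ms) shared across tests."""
    cfg = SimulationConfig(
        species=[SpeciesSpec(4.1e-3, 5.0, 3000.0)],
        duration=30.0,
        bin_width=2e-4,
        seed=42,
    )
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def single_species_curve(single_species_trace):
    return autocorrelate(single_species_trace, max_lag=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
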