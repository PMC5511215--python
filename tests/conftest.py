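import numpy as np
import pytest

import mcfret as m


@pytest.fixture(scope="session")
def photo():
    """Default probe photophysics shared across tests."""
    return m.default_photophysics()


@pytest.fixture(scope="session")
def nanodomain_layout():
    """A representative packed layout (R_D 8 nm, Ar 0.37, 200 nm box)."""
    return m.place_domains(200.0, 8.0, 0.37, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
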