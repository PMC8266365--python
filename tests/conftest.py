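import numpy as np
import pytest

from epicontext.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One shared simulated study at the default desk-scale conditions."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
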