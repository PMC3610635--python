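import numpy as np
import pytest

from itamnet.constructs import ConcentrationTotals, RateSet, preset_construct
from itamnet.network import generate_network
from itamnet.steady_state import build_rate_system


@pytest.fixture(scope="session")
def rates():
    return RateSet()


@pytest.fixture(scope="session")
def totals():
    return ConcentrationTotals()


@pytest.fixture(scope="session")
def z123():
    return preset_construct("z123")


@pytest.fixture(scope="session")
def z123_network(z123, rates):
    return generate_network(z123, rates)


@pytest.fixture(scope="session")
def z123_system(z123_network):
    return build_rate_system(z123_network)


@pytest.fixture(scope="session")
def coarse_grid():
    """A 41-point sweep grid; fine enough for stable Hill fits, cheap
    enough to keep multi-construct comparisons fast."""
    return np.linspace(-2.0, 2.0, 41)
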