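import numpy as np
import pytest

from fdgkin.synthetic_data import ProtocolSpec, make_fixture


@pytest.fixture(scope="session")
def scan():
    """Canonical 300-s-infusion synthetic scan (noise-free + 10 noisy TACs)."""
    return make_fixture(0)


@pytest.fixture(scope="session")
def scan_900():
    """Same truth under a 900-s equal-dose infusion."""
    return make_fixture(0, protocol=ProtocolSpec(duration=900.0))


@pytest.fixture(scope="session")
def scan_bolus():
    """Same truth under a 10-s bolus."""
    return make_fixture(0, protocol=ProtocolSpec(duration=10.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
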