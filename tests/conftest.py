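import numpy as np
import pytest

from hbaccess.inputs import default_input_field


@pytest.fixture(scope="session")
def field():
    """Default study-condition input field (20-60 %EL, 0-17 min)."""
    return default_input_field()


@pytest.fixture(scope="session")
def signature_field():
    """Input field restricted to the onset-metric window 20-37.5 %EL."""
    return default_input_field(positions=np.arange(20.0, 37.5 + 1e-9, 2.5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
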