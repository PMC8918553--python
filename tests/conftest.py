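import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allelerx.amplicon_quant import default_signatures
from allelerx.synthetic_data import default_amplicon_templates

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def templates():
    """(wt, mut) synthetic amplicon templates with centered signatures."""
    return default_amplicon_templates()


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)
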