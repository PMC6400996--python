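import numpy as np
import pytest

from ucmgait.geometric_model import default_chain
from ucmgait.io_gait import TrialMeta
from ucmgait.synthetic_data import SimulationSpec, generate_ensemble


@pytest.fixture
def chain():
    return default_chain()


@pytest.fixture
def meta():
    return TrialMeta("s01", "I-FRT", "pre", "US")


@pytest.fixture
def spec():
    return SimulationSpec(seed=0)


@pytest.fixture
def small_ensemble(spec, meta):
    """20-step ensemble with the default variance structure (seeded)."""
    return generate_ensemble(spec, meta, np.random.default_rng(42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
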