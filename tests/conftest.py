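import numpy as np
import pytest

from toporsa import GroundTruthSpec, generate_condition_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_conditions():
    """20 conditions, 4 per category."""
    return generate_condition_set(20, seed=7)


@pytest.fixture
def default_spec():
    return GroundTruthSpec(seed=42)
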