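import numpy as np
import pytest

from psdnano import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_geometry():
    """Bracelet geometry without background, always bracelet-positive."""
    return simulate.BraceletGeometry(background_density=0.0, bracelet_probability=1.0)
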