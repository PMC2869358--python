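import numpy as np
import pytest

from rescuesim.config import make_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A quick-running configuration on a 10^3 membrane."""
    return make_config(**{
        "grid.extents": (10, 10, 10),
        "engine.max_steps": 200,
        "engine.growth_step_cap": 1500,
    })


def quick_config(**overrides):
    base = {
        "grid.extents": (10, 10, 10),
        "engine.max_steps": 200,
        "engine.growth_step_cap": 1500,
    }
    base.update(overrides)
    return make_config(**base)
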