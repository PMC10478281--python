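import numpy as np
import pytest

from regsct.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A 64x64 phantom spec, the workhorse size for fast tests."""
    return PhantomSpec(grid_size=64)


@pytest.fixture
def plain_spec():
    """Deterministic three-tissue phantom: no jitter, no cavities."""
    return PhantomSpec(grid_size=64, shape_jitter=0.0, n_air_cavities=0)
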