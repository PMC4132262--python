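import numpy as np
import pytest

from fabrefine.synthetic_data import make_toy_fab


@pytest.fixture(scope="session")
def toy_fab():
    """Session-wide deterministic toy structure (two chains, 4-helix bundle)."""
    return make_toy_fab(seed=1)


@pytest.fixture(scope="session")
def toy_fab_copy(toy_fab):
    """An independently built copy (same seed) for dual-context scans."""
    return make_toy_fab(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140814)
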