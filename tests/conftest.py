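import numpy as np
import pytest

from cfswm import design, synthetic_fmri


@pytest.fixture(scope="session")
def exp1():
    return design.build_design(1)


@pytest.fixture(scope="session")
def exp3():
    return design.build_design(3)


@pytest.fixture(scope="session")
def small_grid():
    """Desk-scale grid used throughout the decoding tests."""
    return synthetic_fmri.default_grid((16, 16, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(20220606)
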