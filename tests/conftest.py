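import warnings

import numpy as np
import pytest

from pasvd import FilterConfig, PhantomConfig, blockwise_filter, simulate_phantom
from pasvd.masking import detect_stationary_pa


@pytest.fixture(scope="session")
def phantom():
    """Default phantom simulation shared across the suite (expensive)."""
    return simulate_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def us_components(phantom):
    us, _, _ = phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return blockwise_filter(us, FilterConfig())


@pytest.fixture(scope="session")
def detection(phantom, us_components):
    _, pa, _ = phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return detect_stationary_pa(us_components, pa)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
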