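import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msdiv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)


@pytest.fixture(scope="session")
def default_map():
    """The standard 75-locus chromosome: 1 selected + 37 log-spaced neutral
    flanks per side, 10^-3 to 10 cM."""
    return msdiv.build_flanking_map()


@pytest.fixture(scope="session")
def tiny_map():
    """3-locus degenerate map: neutral at -10, selected at 0, neutral at +10."""
    return msdiv.build_flanking_map(n_flank_per_side=1, min_cM=10.0, max_cM=10.0)
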