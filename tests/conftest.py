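import numpy as np
import pandas as pd
import pytest

from berryopt import (
    FactorialDesign,
    ResponseSurfaceSpec,
    published_network,
    simulate,
)
from berryopt.pareto import load_reference_front, load_reference_validation


@pytest.fixture(scope="session")
def reference_front() -> pd.DataFrame:
    return load_reference_front()


@pytest.fixture(scope="session")
def reference_validation() -> pd.DataFrame:
    return load_reference_validation().set_index("kind")


@pytest.fixture(scope="session")
def published_net():
    return published_network()


@pytest.fixture(scope="session")
def noisefree_table() -> pd.DataFrame:
    """Noise-free replicated factorial table (240 rows of exact ground truth)."""
    return simulate(FactorialDesign(), ResponseSurfaceSpec(noise_cv=0.0), seed=101)


@pytest.fixture(scope="session")
def noisy_table() -> pd.DataFrame:
    """Default-noise synthetic experiment table."""
    return simulate(FactorialDesign(), ResponseSurfaceSpec(noise_cv=0.03), seed=101)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
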