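import numpy as np
import pytest

from gelsig import (
    PercolationParams,
    ProbeSpec,
    elasticity_from_percolation,
    sample_exponent_field,
)


@pytest.fixture(scope="session")
def probe() -> ProbeSpec:
    return ProbeSpec()


@pytest.fixture(scope="session")
def default_params() -> PercolationParams:
    return PercolationParams()


@pytest.fixture(scope="session")
def baseline_map(default_params):
    """A 48x48 log-normal elasticity map with fixed seed."""
    field = sample_exponent_field(shape=(48, 48), seed=1234)
    return elasticity_from_percolation(field, default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
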