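import numpy as np
import pytest

from imdsim import (
    Environment,
    EnvironmentSpec,
    ImdParameters,
    WalkConfig,
    generate_environment,
)


@pytest.fixture(scope="session")
def default_params():
    return ImdParameters()


@pytest.fixture(scope="session")
def sterile_env():
    return generate_environment(EnvironmentSpec(density=0, size=50, seed=1))


@pytest.fixture(scope="session")
def saturated_env():
    """One colony in every cell of a 10x10 lattice."""
    spec = EnvironmentSpec(density=100, patchiness=100, size=10, seed=1)
    return Environment(spec=spec, counts=np.ones((10, 10), dtype=np.int64))


@pytest.fixture(scope="session")
def small_env():
    return generate_environment(EnvironmentSpec(density=60, patchiness=3, size=50, seed=7))


@pytest.fixture
def short_walks():
    return WalkConfig(n_steps=300, n_walks=5, seed=11)
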