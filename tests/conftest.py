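import numpy as np
import pytest

from tadcord import (
    GradientField, InteractionParams, NoiseSpec, build_standard_environment,
    make_measurement_tables,
)


@pytest.fixture(scope="session")
def std_env():
    return build_standard_environment()


@pytest.fixture(scope="session")
def tract_env():
    """Standard environment with both dorsal-tract barriers full length."""
    return build_standard_environment(dl_barrier_x_start=500.0)


@pytest.fixture(scope="session")
def default_field():
    return GradientField()


@pytest.fixture(scope="session")
def tables():
    return make_measurement_tables(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def no_interaction():
    return InteractionParams(0.0, 0.0, 1.0)
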