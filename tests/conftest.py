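import numpy as np
import pytest

from faniche.synthetic_data import (
    RasterSpec,
    SyntheticScenario,
    make_mean_shape,
    simulate_study,
)


@pytest.fixture(scope="session")
def skull():
    """Unit-size symmetric 40-landmark mean shape (17 pairs + 6 midline)."""
    mean, sym = make_mean_shape(17, 6)
    return mean, sym


@pytest.fixture(scope="session")
def small_shape():
    mean, sym = make_mean_shape(4, 2)
    return mean, sym


@pytest.fixture(scope="session")
def small_study():
    """A compact complete study: 8 populations, 10 specimens each."""
    scenario = SyntheticScenario(
        n_pops=8,
        n_per_pop=10,
        n_replicated=6,
        raster_spec=RasterSpec(nrows=30, ncols=30),
        seed=11,
    )
    return simulate_study(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
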