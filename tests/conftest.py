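import numpy as np
import pytest

import phenomap as pm


@pytest.fixture(scope="session")
def flat_world():
    """Noiseless constant-coefficient world: the exactness regime."""
    return pm.make_world(sigma=0.0, beta=0.0, seed=101, shape=(20, 20))


@pytest.fixture(scope="session")
def flat_obs(flat_world):
    """Float-DOY observations lying exactly on the true plane."""
    return pm.sample_observations(flat_world, 80, years=np.array([2019]),
                                  seed=102, round_doy=False)


@pytest.fixture(scope="session")
def noisy_world():
    return pm.make_world(sigma=6.0, beta=0.0, seed=103, shape=(20, 20))


@pytest.fixture(scope="session")
def noisy_obs(noisy_world):
    return pm.sample_observations(noisy_world, 200, years=np.array([2019]),
                                  seed=104)


@pytest.fixture
def small_geom():
    return pm.GridGeometry(north=50.0, west=10.0, dlat=0.5, dlon=0.5,
                           nrows=3, ncols=3)
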