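import numpy as np
import pytest

import reefrange as rr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def red_grouper():
    return rr.get_species("red_grouper")


@pytest.fixture(scope="session")
def mutton_snapper():
    return rr.get_species("mutton_snapper")


@pytest.fixture(scope="session")
def array32():
    """Default 32-receiver staggered array."""
    return rr.staggered_array()


@pytest.fixture(scope="session")
def grid3x3():
    return rr.staggered_array(n_rows=3, n_cols=3, spacing=600.0)


@pytest.fixture(scope="session")
def short_tracks(array32):
    """One month of red grouper tracks for three fish (session-cached)."""
    params = rr.get_species("red_grouper")
    world = rr.default_world(center=tuple(array32.positions.mean(axis=0)))
    agents = rr.instantiate_cohort(world, array32, params)[:3]
    return rr.run_simulation(world, agents, duration=30 * 86400, rng=777)


@pytest.fixture(scope="session")
def tracked_fish():
    return rr.load_tracked_fish()
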