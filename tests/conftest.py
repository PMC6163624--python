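import numpy as np
import pytest

import riskpipe as rp


@pytest.fixture(scope="session")
def profile():
    return rp.make_profile(7, user_id="u1")


@pytest.fixture(scope="session")
def short_normal(profile):
    """Ten minutes of normal-conditions data (8 Hz motion, all sensors)."""
    return rp.simulate_normal(profile, 600, seed=3)


@pytest.fixture(scope="session")
def time_matrix(short_normal):
    return rp.extract_matrix([short_normal], mode="time")


@pytest.fixture(scope="session")
def small_cohort():
    """Two users, 20 min normal data each, all five scenarios."""
    return rp.build_cohort(2, seed=42, ncds_seconds=1200)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
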