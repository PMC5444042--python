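import numpy as np
import pytest

import activeness as act


@pytest.fixture(scope="session")
def profile():
    """Small default-parameter user used across tests (5 days)."""
    return act.UserProfile(seed=11, duration_days=5)


@pytest.fixture(scope="session")
def user_data(profile):
    return act.simulate_user(profile)


@pytest.fixture(scope="session")
def raw_series(profile, user_data):
    hr_log, episodes = user_data
    return act.build_raw_series(hr_log, episodes, profile.start, profile.n_minutes)


@pytest.fixture(scope="session")
def norm_series(raw_series):
    series, _spec = act.preprocess(raw_series)
    return series


@pytest.fixture(scope="session")
def norm_spec(raw_series):
    _series, spec = act.preprocess(raw_series)
    return spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
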