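import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fedaffect import (  # noqa: E402
    FeatureTable,
    SyntheticConfig,
    generate_feature_population,
)


@pytest.fixture(scope="session")
def small_population():
    """5 users x 30 windows: quick, heterogeneous, deterministic."""
    cfg = SyntheticConfig(n_users=5, windows_per_user=30, seed=11)
    table, truth = generate_feature_population(cfg)
    return table, truth


@pytest.fixture(scope="session")
def default_population():
    """The full default cohort: 15 users x 72 windows."""
    cfg = SyntheticConfig(seed=3)
    table, truth = generate_feature_population(cfg)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
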