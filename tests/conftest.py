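import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riskval.simulate import default_config, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    return default_config()


@pytest.fixture(scope="session")
def roster(sim_config):
    """Default-sized synthetic roster, with prior-diagnosis flags and missingness."""
    return generate_cohort(sim_config, seed=20_240_101)


@pytest.fixture(scope="session")
def complete_roster(sim_config):
    """Synthetic roster without injected missingness."""
    return generate_cohort(sim_config, seed=20_240_202, inject_missing=False)


def make_preds(seed: int, n: int = 200, ties: bool = False):
    """Random prediction set with both outcome classes present."""
    rng = np.random.default_rng(seed)
    p = rng.random(n)
    if ties:
        p = np.round(p, 1)
    y = (rng.random(n) < np.clip(p + rng.normal(0, 0.3, n), 0.02, 0.98)).astype(float)
    if y.min() == y.max():  # force both classes
        y[0], y[-1] = 0.0, 1.0
    return p, y
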