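import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: single suite-wide base seed
SEED = 1


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-sow default-calibration cohort shared across tests."""
    import sowpatterns as sp

    cfg = sp.default_sim_config(n_sows=6, seed=SEED)
    return sp.build_cohort(cfg)
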