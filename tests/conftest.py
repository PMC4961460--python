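import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import graspspace as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return g.make_condition_catalog()


@pytest.fixture(scope="session")
def tiny_session():
    """Small but complete session: all 50 conditions, 3 trials each, 18 units."""
    cfg = g.GeneratorConfig(
        unit_counts={"AIP": 6, "F5": 6, "M1": 6}, trials_per_condition=3
    )
    return g.generate_session(cfg, seed=11)


@pytest.fixture(scope="session")
def structured_session():
    """Mid-sized session with the default tuning structure (10 trials/cond)."""
    cfg = g.GeneratorConfig(unit_counts={"AIP": 20, "F5": 20, "M1": 20})
    return g.generate_session(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
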