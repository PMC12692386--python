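import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import molmutbench as mmb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seed_set():
    """A small synthetic seed population shared across tests."""
    return mmb.generate_seed_set(60, rng_seed=123)


@pytest.fixture(scope="session")
def seed_set_500():
    """The benchmark-scale 500-molecule synthetic seed population."""
    return mmb.generate_seed_set(500, rng_seed=0)


@pytest.fixture(scope="session")
def random_molecules():
    """100 random grammar-derived molecules of assorted sizes (no size floor)."""
    return mmb.generate_seed_set(100, min_tokens=5, max_tokens=40,
                                 rng_seed=7, min_heavy_atoms=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
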