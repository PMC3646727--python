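import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ibdhist as ih

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def gmap():
    """Default 22-autosome, 32 Morgan map."""
    return ih.default_map()


@pytest.fixture(scope="session")
def toy_map():
    """Two equal chromosomes totalling 2 Morgans; fast analytic tests."""
    return ih.uniform_map(2, 2.0)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid covering the recent past, for quick fits."""
    return ih.make_time_grid(40, 400.0)


@pytest.fixture(scope="session")
def channel():
    return ih.named_channel("fastibd")
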