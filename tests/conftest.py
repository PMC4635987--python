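import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t2dm_cesim import fixtures

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_cfg():
    """The packaged base-case configuration (validated)."""
    return fixtures.make_base_case_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
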