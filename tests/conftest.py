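import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def cerebral_cohort():
    """One cerebral synthetic cohort (LZR + OZR) shared across tests."""
    from vhi.model import Bed, Group
    from vhi.synthdata import default_spec, generate_cohort

    spec = default_spec(bed=Bed.CEREBRAL, groups=[Group.LZR, Group.OZR])
    return spec, generate_cohort(spec, seed=11)
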