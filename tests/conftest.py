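import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avmech import ElasticParams, ViscousParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ref_elastic() -> ElasticParams:
    """Reference porcine-valve elastic parameter set."""
    return ElasticParams(alpha=0.0217, beta=1.389, k1=0.5853, k2=0.4250)


@pytest.fixture
def ref_viscous() -> dict[float, ViscousParams]:
    """Reference per-rate viscosities."""
    return {
        0.01: ViscousParams(6.082, 273.2, rate=0.01),
        0.1: ViscousParams(1.821, 58.75, rate=0.1),
        0.5: ViscousParams(0.3771, 16.68, rate=0.5),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170111)
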