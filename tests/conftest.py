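import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from idioloc import (BodyShape, ErrorModel, MotionConfig,  # noqa: E402
                     make_standard_arena)


@pytest.fixture(scope="session")
def kite():
    return make_standard_arena("kite")


@pytest.fixture(scope="session")
def circle():
    return make_standard_arena("circle")


@pytest.fixture(scope="session")
def square():
    return make_standard_arena("square")


@pytest.fixture(scope="session")
def egg():
    return make_standard_arena("egg")


@pytest.fixture(scope="session")
def circle_barrier():
    return make_standard_arena("circle_barrier")


@pytest.fixture(scope="session")
def calibrated():
    return ErrorModel.calibrated()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ellipse_body():
    return BodyShape((7.5, 3.5))


@pytest.fixture(scope="session")
def motion_cfg():
    return MotionConfig()
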