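import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from depthprop import CameraModel, default_camera

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    return default_camera()


@pytest.fixture(scope="session")
def small_cam() -> CameraModel:
    """A 64x48 camera with the same mounting geometry, for cheap renders."""
    return CameraModel(
        fx=57.0, fy=57.0, cx=31.5, cy=23.5, width=64, height=48,
        h_c=0.45, alpha=math.radians(35.0),
    )


@pytest.fixture(scope="session")
def simple_cam() -> CameraModel:
    """The textbook configuration used by the worked examples:
    h_c = 1 m, 30 degree tilt."""
    return CameraModel(
        fx=100.0, fy=100.0, cx=49.5, cy=49.5, width=100, height=100,
        h_c=1.0, alpha=math.radians(30.0),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
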