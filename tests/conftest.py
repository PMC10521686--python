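import numpy as np
import pytest

from lumiplan import EmitterSpec, FiberPose, PlaneGrid, UFOVSpec
from lumiplan.reference import (
    FIBER_HALF_ANGLES_DEG,
    HIGH_AR_POSES,
    HIGH_AR_UFOV,
    LOW_AR_POSES,
    LOW_AR_UFOV,
    reference_emitters,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def emitters():
    return reference_emitters()


@pytest.fixture(scope="session")
def low_ar_poses():
    return list(LOW_AR_POSES)


@pytest.fixture(scope="session")
def high_ar_poses():
    return list(HIGH_AR_POSES)


@pytest.fixture(scope="session")
def low_ar_ufov():
    return LOW_AR_UFOV


@pytest.fixture(scope="session")
def high_ar_ufov():
    return HIGH_AR_UFOV


def random_pose(rng) -> FiberPose:
    return FiberPose(
        R=rng.uniform(5.0, 40.0),
        theta=rng.uniform(0.0, 70.0),
        phi=rng.uniform(0.0, 360.0),
        dx=rng.uniform(-5.0, 5.0),
        dy=rng.uniform(-5.0, 5.0),
    )
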