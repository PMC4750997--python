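import numpy as np
import pytest

from stiffsynth import Posture, make_default_arm, make_single_joint_limb, osu_gomi_basis


@pytest.fixture(scope="session")
def arm():
    return make_default_arm()


@pytest.fixture(scope="session")
def posture01():
    """Elbow-positive posture placing the endpoint at (0, 1)."""
    return Posture.from_degrees(30.0, 120.0)


@pytest.fixture(scope="session")
def single_joint():
    """One-joint, three-muscle limb with moment arms (1, 2, -1)."""
    return make_single_joint_limb((1.0, 2.0, -1.0))


@pytest.fixture(scope="session")
def basis():
    return osu_gomi_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_posture(rng, min_sin=0.1):
    """Non-singular posture drawn uniformly over a safe elbow range."""
    while True:
        t1 = rng.uniform(-np.pi, np.pi)
        t2 = rng.uniform(-np.pi, np.pi)
        if abs(np.sin(t2)) >= min_sin:
            return Posture((t1, t2))
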