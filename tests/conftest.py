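import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from levator_ica.frame import LandmarkSet
from levator_ica.phantom import PhantomSpec, generate_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def axis_landmarks() -> LandmarkSet:
    """Axis-aligned pelvis: PICS axis = +y, lateral = +x, vertical = +z."""
    return LandmarkSet(
        pubic_symphysis=(0.0, 0.0, 0.0),
        sacrococcygeal_joint=(0.0, 100.0, 0.0),
        ischial_spine_left=(50.0, 60.0, -10.0),
        ischial_spine_right=(-50.0, 60.0, -10.0),
    )


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Noise-free 45/45-degree phantom: ground-truth total = 90 everywhere."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def varied_phantom():
    """Phantom with different prescribed angles at every plane and side."""
    spec = PhantomSpec(left_angles=(10, 25, 40, 55, 70), right_angles=(65, 50, 40, 30, 15))
    return generate_phantom(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix from a QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
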