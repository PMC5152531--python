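import numpy as np
import pytest

from rvquant.geometry import LandmarkSet, RigidTransform
from rvquant.segments import build_axis_frame
from rvquant.synthetic import PhantomParams, make_rv_phantom


def random_landmarks(rng: np.random.Generator) -> LandmarkSet:
    """A plausible, well-spread landmark set with random jitter (mm)."""
    L = rng.uniform(45.0, 70.0)
    ra = rng.uniform(15.0, 25.0)
    rb = rng.uniform(15.0, 25.0)
    jit = lambda: rng.normal(0.0, 1.5, size=3)
    return LandmarkSet.from_mapping({
        "valve_center": np.array([0.0, 0.0, L]) + jit(),
        "annulus_inferior": np.array([0.0, rb, L]) + jit(),
        "annulus_anterior": np.array([0.0, -rb, L]) + jit(),
        "annulus_left": np.array([-ra, 0.0, L]) + jit(),
        "annulus_right": np.array([ra, 0.0, L]) + jit(),
        "apex": jit(),
    })


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def random_transform(rng: np.random.Generator,
                     max_translation: float = 30.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng),
                          rng.uniform(-max_translation, max_translation, 3))


@pytest.fixture(scope="session")
def phantom50():
    """Default 50 ml globular phantom at 1 mm spacing, with landmarks."""
    return make_rv_phantom(PhantomParams(target_volume_ml=50.0, spacing=1.0))


@pytest.fixture(scope="session")
def frame50(phantom50):
    _, landmarks = phantom50
    return build_axis_frame(landmarks)
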