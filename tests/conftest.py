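import numpy as np
import pytest

from orchardnbv import Box3D, GaussianField, GaussianObstacle, RigidTransform
from scipy.spatial.transform import Rotation


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    return RigidTransform(random_rotation(rng), rng.uniform(-2, 2, 3))


def random_gaussian(
    rng: np.random.Generator, scale=2.0, s_range=(0.05, 0.5)
) -> GaussianObstacle:
    return GaussianObstacle(
        rng.uniform(-scale, scale, 3),
        random_rotation(rng),
        rng.uniform(*s_range, 3),
    )


def random_field(
    rng: np.random.Generator, n: int, scale=2.0, s_range=(0.05, 0.5)
) -> GaussianField:
    return GaussianField([random_gaussian(rng, scale, s_range) for _ in range(n)])


def random_box(rng: np.random.Generator, span=1.0, max_extent=0.5) -> Box3D:
    return Box3D(
        rng.uniform(-span, span, 3),
        rng.uniform(0.05, max_extent, 3),
        confidence=float(rng.uniform()),
        class_id=int(rng.integers(0, 2)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
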