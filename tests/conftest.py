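import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coxaplan.core import RigidTransform
from coxaplan.synthetic_data import FemurParams, generate_femur


@pytest.fixture(scope="session")
def default_femur():
    """One default synthetic femur (head r 10, neck 35 mm, 135/20 deg)."""
    return generate_femur(FemurParams())


@pytest.fixture(scope="session")
def coarse_femur():
    """Coarser mesh for tests that only need topology/plumbing."""
    return generate_femur(FemurParams(mesh_pitch=0.7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return RigidTransform(rotation=R.as_matrix(),
                          translation=rng.uniform(-50, 50, 3))
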