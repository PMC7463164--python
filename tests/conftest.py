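import numpy as np
import pytest

from optoreg.geometry_io import MNI, LandmarkSet, SurfaceMesh
from optoreg.synthetic_data import SyntheticHeadSpec, make_cap, make_head


@pytest.fixture(scope="session")
def default_head():
    return make_head()


@pytest.fixture(scope="session")
def default_cap(default_head):
    return make_cap(default_head)


@pytest.fixture(scope="session")
def unit_sphere_head():
    return make_head(SyntheticHeadSpec(semi_axes=(1.0, 1.0, 1.0),
                                       cortex_shrink=0.8, subdivisions=2))


@pytest.fixture
def square_mesh():
    """Two triangles tiling the unit square in the z=0 plane (MNI frame)."""
    vertices = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0],
    ])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(vertices, faces, MNI)


@pytest.fixture
def mni_landmarks():
    """A non-coplanar MNI-frame landmark set at head-like positions."""
    return LandmarkSet.from_arrays(
        [[0, 95, 0], [0, -95, 0], [0, 0, 80], [-85, 0, 0], [85, 0, 0]], MNI)


def random_affine(rng, max_condition=100.0):
    """A random invertible 3x3 linear part (condition < max_condition) + t."""
    while True:
        linear = rng.normal(size=(3, 3))
        if np.linalg.cond(linear) < max_condition:
            break
    return linear, rng.normal(scale=50.0, size=3)
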