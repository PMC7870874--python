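import numpy as np
import pytest

from actseg.geometry import PointCloud, SurfaceMesh, Volume, compute_normals, icosphere
from actseg.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_volume():
    """8x8x8 ramp volume with identity affine."""
    data = np.arange(8 * 8 * 8, dtype=float).reshape(8, 8, 8)
    return Volume(data, np.eye(4))


@pytest.fixture
def sphere_mesh():
    return compute_normals(icosphere(2, radius=10.0, center=(1.0, 2.0, 3.0)))


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.normal(size=(20, 3)) * 10.0)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic phantom reused by read-only tests."""
    spec = PhantomSpec(seed=7)
    vol, mesh, labels = generate_phantom(spec)
    return spec, vol, mesh, labels


def cube_mesh(size: float = 1.0):
    """Axis-aligned unit cube triangulated with 12 faces."""
    pts = np.array(
        [[x, y, z] for x in (0, size) for y in (0, size) for z in (0, size)], dtype=float
    )
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x=0
            [4, 6, 7], [4, 7, 5],  # x=1
            [0, 4, 5], [0, 5, 1],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=1
            [0, 2, 6], [0, 6, 4],  # z=0
            [1, 5, 7], [1, 7, 3],  # z=1
        ]
    )
    return SurfaceMesh(pts, None, faces)
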