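import numpy as np
import pytest

from fiducialign import FiducialSpec, TriangleMesh, make_cross_marker, make_sphere_marker


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sphere_marker():
    return make_sphere_marker(10.0, 3)


@pytest.fixture(scope="session")
def cross_marker():
    return make_cross_marker(FiducialSpec(kind="cross"))


def grid_plane(z=0.0, n=11, size=100.0, name="plane"):
    """n x n vertex grid plane at height z, spanning [0, size]^2."""
    xs = np.linspace(0.0, size, n)
    X, Y = np.meshgrid(xs, xs)
    verts = np.stack([X.ravel(), Y.ravel(), np.full(n * n, float(z))], axis=1)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            q = i * n + j
            faces.append([q, q + n, q + n + 1])
            faces.append([q, q + n + 1, q + 1])
    return TriangleMesh(verts, np.asarray(faces), name)


def unit_cube():
    """Watertight unit cube [0,1]^3 with outward winding."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (-z)
            [4, 5, 6], [4, 6, 7],  # top (+z)
            [0, 1, 5], [0, 5, 4],  # front (-y)
            [2, 3, 7], [2, 7, 6],  # back (+y)
            [1, 2, 6], [1, 6, 5],  # right (+x)
            [3, 0, 4], [3, 4, 7],  # left (-x)
        ]
    )
    return TriangleMesh(v, f, "cube")


@pytest.fixture
def plane_mesh():
    return grid_plane()


@pytest.fixture
def cube_mesh():
    return unit_cube()
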