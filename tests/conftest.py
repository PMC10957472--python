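import numpy as np
import pytest

from upekit.mesh_core import build_mesh
from upekit.synthetic_data import make_template


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron with edge length 1."""
    v = np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    ) / (2.0 * np.sqrt(2.0))
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return build_mesh(v, f)


@pytest.fixture
def unit_cube():
    """Axis-aligned unit cube, 12 outward-wound triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],        # x = 0
            [4, 7, 5], [4, 6, 7],        # x = 1
            [0, 4, 5], [0, 5, 1],        # y = 0
            [2, 7, 6], [2, 3, 7],        # y = 1
            [0, 6, 4], [0, 2, 6],        # z = 0
            [1, 5, 7], [1, 7, 3],        # z = 1
        ]
    )
    return build_mesh(v, f)


@pytest.fixture(scope="session")
def small_template():
    """162-vertex LV-like template (fast tests)."""
    return make_template(1)


@pytest.fixture(scope="session")
def default_template():
    """642-vertex LV-like template."""
    return make_template(2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def triangle_strip(n_vertices: int):
    """A flat strip of triangles: vertex i connects to i-1, i-2 (path-like
    chain mesh used where a 1D graph with valid faces is needed)."""
    t = np.linspace(0.0, 1.0, n_vertices)
    v = np.column_stack([t, (np.arange(n_vertices) % 2) * 0.1, np.zeros(n_vertices)])
    f = np.array([[i, i + 1, i + 2] for i in range(n_vertices - 2)])
    return build_mesh(v, f)
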