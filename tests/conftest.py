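import numpy as np
import pytest
import trimesh

from paleoretro._mesh import make_mesh
from paleoretro.synthetic import CalvariumParams, generate_calvarium


@pytest.fixture(scope="session")
def calvarium():
    """Coarse symmetric vault fixture (shared; treat as read-only)."""
    return generate_calvarium(CalvariumParams(resolution=8.0, seed=0))


@pytest.fixture(scope="session")
def sphere30():
    s = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
    return make_mesh(s.vertices, s.faces)


@pytest.fixture(scope="session")
def sphere10():
    s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return make_mesh(s.vertices, s.faces)


@pytest.fixture(scope="session")
def sphere12():
    s = trimesh.creation.icosphere(subdivisions=3, radius=12.0)
    return make_mesh(s.vertices, s.faces)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def plane_grid_mesh(half: float = 10.0, n: int = 21):
    g = np.linspace(-half, half, n)
    gx, gy = np.meshgrid(g, g)
    v = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n + 1])
            faces.append([a, a + n + 1, a + n])
    return make_mesh(v, np.array(faces, dtype=np.int64))


@pytest.fixture
def plane_mesh():
    return plane_grid_mesh()
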