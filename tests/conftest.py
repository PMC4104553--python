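import numpy as np
import pytest
from scipy.spatial import Delaunay

from tonosurf.mesh import TriangleMesh
from tonosurf.simulate import grid_mesh, make_stp_phantom


@pytest.fixture
def square_mesh():
    """Unit square split into two triangles along one diagonal."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(verts, tris)


@pytest.fixture
def centered_rect_mesh():
    """4x2 mm rectangle with a center vertex: every vertex pair is joined by
    a straight edge path, so the graph metric equals the Euclidean metric."""
    verts = np.array(
        [[0, 0, 0], [4, 0, 0], [4, 2, 0], [0, 2, 0], [2, 1, 0]], float
    )
    tris = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    return TriangleMesh(verts, tris)


def random_delaunay_mesh(n_points: int, seed: int, scale: float = 10.0) -> TriangleMesh:
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, scale, (n_points, 2))
    tri = Delaunay(pts).simplices
    verts = np.column_stack([pts, np.zeros(n_points)])
    return TriangleMesh(verts, tri)


@pytest.fixture
def random_patch():
    return random_delaunay_mesh(20, seed=42)


@pytest.fixture
def plane_mesh():
    """9x9 regular planar grid."""
    return grid_mesh(np.linspace(0, 8, 9), np.linspace(0, 8, 9))


@pytest.fixture(scope="session")
def small_phantom():
    return make_stp_phantom(20, 12, fold_depth_mm=3.0, seed=5)


@pytest.fixture(scope="session")
def flat_phantom():
    return make_stp_phantom(20, 12, fold_depth_mm=0.0, seed=5)
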