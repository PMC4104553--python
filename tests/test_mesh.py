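import networkx as nx
import numpy as np
import pytest
import trimesh

from tonosurf.mesh import (
    ScalarField,
    TriangleMesh,
    edge_graph,
    geodesic_distances,
    geodesic_gaussian_smooth,
    mean_curvature,
    pairwise_geodesic_distances,
    vertex_normals,
)
from tonosurf.simulate import grid_mesh

from conftest import random_delaunay_mesh


def icosphere_mesh(radius=1.0, subdivisions=3):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


class TestMeshInvariants:
    def test_rejects_out_of_range_index(self):
        with pytest.raises(ValueError, match="index"):
            TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_rejects_repeated_vertex(self):
        with pytest.raises(ValueError, match="repeats"):
            TriangleMesh(np.eye(3), np.array([[0, 1, 1]]))

    def test_rejects_zero_area_triangle(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="area"):
            TriangleMesh(verts, np.array([[0, 1, 2]]))

    def test_rejects_disconnected_mesh(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0], [6, 5, 0], [5, 6, 0]],
            float,
        )
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        with pytest.raises(ValueError, match="disconnected"):
            TriangleMesh(verts, tris)


class TestEdgeGraph:
    def test_two_triangle_square(self, square_mesh):
        g = edge_graph(square_mesh)
        assert g.number_of_edges() == 5
        weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
        assert np.allclose(weights, [1, 1, 1, 1, np.sqrt(2)])

    def test_edge_count_bound(self, small_phantom):
        mesh, _ = small_phantom
        g = edge_graph(mesh)
        assert g.number_of_edges() <= 3 * mesh.n_triangles

    def test_weights_are_vertex_distances(self, random_patch):
        g = edge_graph(random_patch)
        for a, b, d in g.edges(data=True):
            expected = np.sqrt(
                np.sum((random_patch.vertices[a] - random_patch.vertices[b]) ** 2)
            )
            assert d["weight"] == pytest.approx(expected, abs=1e-12)


class TestGeodesics:
    def test_straight_path_distance(self):
        mesh = grid_mesh(np.arange(3.0), np.arange(2.0))
        d = geodesic_distances(mesh, [0])
        # vertex layout: (x,y) = (i, j); (2, 0) is two unit edges from (0, 0)
        idx_20 = np.flatnonzero(
            (mesh.vertices[:, 0] == 2) & (mesh.vertices[:, 1] == 0)
        )[0]
        assert d[idx_20] == pytest.approx(2.0)

    def test_source_distance_zero(self, random_patch):
        d = geodesic_distances(random_patch, [7])
        assert d[7] == 0.0

    def test_empty_sources_error(self, square_mesh):
        with pytest.raises(ValueError, match="empty"):
            geodesic_distances(square_mesh, [])

    @pytest.mark.parametrize("seed,n", [(1, 25), (2, 40), (3, 50)])
    def test_matches_floyd_warshall(self, seed, n):
        mesh = random_delaunay_mesh(n, seed=seed)
        D = pairwise_geodesic_distances(mesh)
        ref = nx.floyd_warshall_numpy(edge_graph(mesh), nodelist=range(n))
        assert np.allclose(D, ref, atol=1e-10)

    def test_triangle_inequality_on_edges(self, random_patch):
        D = pairwise_geodesic_distances(random_patch)
        for a, b, d in edge_graph(random_patch).edges(data=True):
            assert D[a, b] <= d["weight"] + 1e-12


class TestVertexNormals:
    def test_planar_sheet_normals(self, plane_mesh):
        n = vertex_normals(plane_mesh)
        assert np.allclose(n, [0, 0, 1], atol=1e-12)

    def test_unit_length(self, small_phantom):
        mesh, _ = small_phantom
        n = vertex_normals(mesh)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_sphere_normals_radial(self):
        mesh = icosphere_mesh(radius=1.0, subdivisions=2)
        n = vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(np.sum(n * radial, axis=1), -1, 1)))
        assert angles.max() < 5.0

    def test_flip_flag(self, plane_mesh):
        flipped = TriangleMesh(
            plane_mesh.vertices, plane_mesh.triangles, flip_normals=True
        )
        assert np.allclose(vertex_normals(flipped), [0, 0, -1], atol=1e-12)

    def test_isolated_vertex_error(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 9]], float)
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]]), validate=False)
        with pytest.raises(ValueError, match="isolated"):
            vertex_normals(mesh)


class TestMeanCurvature:
    def test_plane_is_flat(self, plane_mesh):
        h = mean_curvature(plane_mesh).values
        interior = ~plane_mesh.boundary_vertices()
        assert np.all(np.abs(h[interior]) < 1e-6)
        assert np.all(np.isnan(h[~interior]))

    def test_sphere_curvature(self):
        mesh = icosphere_mesh(radius=10.0, subdivisions=3)
        h = mean_curvature(mesh).values
        assert np.allclose(h, 0.1, rtol=0.1)

    def test_sign_flips_with_orientation(self):
        mesh = icosphere_mesh(radius=10.0, subdivisions=2)
        rev = TriangleMesh(mesh.vertices, mesh.triangles[:, ::-1])
        assert np.allclose(mean_curvature(rev).values, -mean_curvature(mesh).values)


class TestGeodesicGaussianSmooth:
    def test_constant_preserved(self, small_phantom):
        mesh, _ = small_phantom
        out = geodesic_gaussian_smooth(np.full(mesh.n_vertices, 3.7), mesh, 2.0)
        assert np.allclose(out.values, 3.7)

    def test_impulse_response(self, plane_mesh):
        x = np.zeros(plane_mesh.n_vertices)
        x[40] = 1.0
        out = geodesic_gaussian_smooth(x, plane_mesh, 2.0).values
        assert out.sum() <= 1.0 + 1e-9
        assert np.argmax(out) == 40

    def test_matches_bruteforce_when_untruncated(self, random_patch):
        rng = np.random.default_rng(0)
        x = rng.normal(size=random_patch.n_vertices)
        D = pairwise_geodesic_distances(random_patch)
        fwhm = 3.0 * D.max()  # 3 sigma far beyond the mesh diameter
        sigma = fwhm / 2.3548200450309493
        W = np.exp(-(D**2) / (2 * sigma**2))
        expected = W @ x / W.sum(axis=1)
        out = geodesic_gaussian_smooth(x, random_patch, fwhm).values
        assert np.allclose(out, expected, atol=1e-6)

    def test_masked_vertices_excluded(self, plane_mesh):
        x = np.ones(plane_mesh.n_vertices)
        x[10] = np.nan
        out = geodesic_gaussian_smooth(x, plane_mesh, 2.0).values
        assert np.isnan(out[10])
        ok = ~np.isnan(out)
        assert np.allclose(out[ok], 1.0)

    def test_commutes_with_adding_constant(self, random_patch):
        rng = np.random.default_rng(1)
        x = rng.normal(size=random_patch.n_vertices)
        a = geodesic_gaussian_smooth(x + 5.0, random_patch, 3.0).values
        b = geodesic_gaussian_smooth(x, random_patch, 3.0).values + 5.0
        assert np.allclose(a, b, atol=1e-9)

    def test_invalid_fwhm(self, square_mesh):
        with pytest.raises(ValueError):
            geodesic_gaussian_smooth(np.zeros(4), square_mesh, 0.0)
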