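"""Triangulated cortical surface patches and geometric primitives.

The mesh is the carrier for every per-vertex map in the pipeline (curvature,
best frequency, myelin index).  Geodesic distances are *graph* geodesics:
shortest paths along triangle edges weighted by Euclidean edge length, which
is what surface-based smoothing and flattening in this pipeline are defined
on.  Exact polyhedral geodesics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "TriangleMesh",
    "ScalarField",
    "edge_graph",
    "geodesic_distances",
    "pairwise_geodesic_distances",
    "vertex_normals",
    "mean_curvature",
    "geodesic_gaussian_smooth",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface patch in world millimetres (RAS).

    Parameters
    ----------
    vertices
        (n, 3) float array of vertex positions in mm.
    triangles
        (m, 3) int array of 0-based vertex index triples.
    flip_normals
        If True, vertex/triangle normals are negated so that "outward"
        points away from the designated white-matter side when the stored
        winding has the opposite handedness.
    validate
        Check mesh invariants on construction (valid indices, no degenerate
        triangle, connected edge graph, edge-manifold).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    flip_normals: bool = False
    validate: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        t = np.asarray(self.triangles, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.validate:
            self._check_invariants()

    # -- invariants ------------------------------------------------------
    def _check_invariants(self) -> None:
        n = self.n_vertices
        t = self.triangles
        if t.min(initial=0) < 0 or (t.size and t.max() >= n):
            raise ValueError("triangle index out of range")
        if np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise ValueError("triangle repeats a vertex")
        if np.any(self.triangle_areas() <= 1e-12):
            raise ValueError("zero-area triangle")
        edges, counts = self._edge_multiplicity()
        if np.any(counts > 2):
            raise ValueError("non-manifold edge (shared by more than 2 triangles)")
        adj = self.adjacency_matrix()
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(
                f"mesh edge graph is disconnected ({n_comp} components)"
            )

    # -- basic quantities ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    def triangle_cross(self) -> np.ndarray:
        """Un-normalized triangle normals (cross product, length = 2*area)."""
        p = self.vertices[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return -c if self.flip_normals else c

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def _unique_edges(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def _edge_multiplicity(self):
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0, return_counts=True)

    def boundary_vertices(self) -> np.ndarray:
        """Boolean flag per vertex: lies on an edge used by only 1 triangle."""
        edges, counts = self._edge_multiplicity()
        out = np.zeros(self.n_vertices, dtype=bool)
        out[edges[counts == 1].ravel()] = True
        return out

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Sparse symmetric edge-length matrix over unique triangle edges."""
        e = self._unique_edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        n = self.n_vertices
        return sparse.csr_matrix((np.concatenate([w, w]), (i, j)), shape=(n, n))


@dataclass
class ScalarField:
    """One real value per mesh vertex; NaN marks missing/masked-out vertices."""

    values: np.ndarray
    name: str = ""
    mesh_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("ScalarField values must be 1-D")

    @property
    def mask(self) -> np.ndarray:
        """True where the value is present (not the NaN sentinel)."""
        return np.isfinite(self.values)

    def check_mesh(self, mesh: TriangleMesh) -> None:
        if self.values.shape[0] != mesh.n_vertices:
            raise ValueError(
                f"field length {self.values.shape[0]} != vertex count {mesh.n_vertices}"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def edge_graph(mesh: TriangleMesh) -> nx.Graph:
    """Weighted undirected graph over vertices; weight = edge length in mm."""
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    e = mesh._unique_edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    g.add_weighted_edges_from(
        (int(a), int(b), float(d)) for (a, b), d in zip(e, w)
    )
    if not nx.is_connected(g):
        n_comp = nx.number_connected_components(g)
        raise ValueError(f"mesh edge graph is disconnected ({n_comp} components)")
    return g


def geodesic_distances(
    mesh: TriangleMesh, sources: Iterable[int] | int
) -> np.ndarray:
    """Graph-geodesic distance (mm) from the nearest source to every vertex."""
    if np.isscalar(sources):
        idx = [int(sources)]
    else:
        idx = [int(s) for s in sources]
    if not idx:
        raise ValueError("source set is empty")
    d = dijkstra(mesh.adjacency_matrix(), directed=False, indices=idx, min_only=True)
    return np.asarray(d, dtype=np.float64)


def pairwise_geodesic_distances(mesh: TriangleMesh) -> np.ndarray:
    """All-pairs graph-geodesic distance matrix (repeated single-source Dijkstra)."""
    return np.asarray(
        dijkstra(mesh.adjacency_matrix(), directed=False), dtype=np.float64
    )


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit outward normal per vertex, area-weighted over incident triangles."""
    cross = mesh.triangle_cross()  # length 2*area -> area weighting for free
    acc = np.zeros_like(mesh.vertices)
    cnt = np.zeros(mesh.n_vertices, dtype=np.int64)
    for k in range(3):
        np.add.at(acc, mesh.triangles[:, k], cross)
        np.add.at(cnt, mesh.triangles[:, k], 1)
    if np.any(cnt == 0):
        bad = np.flatnonzero(cnt == 0)
        raise ValueError(f"isolated vertices with no incident triangle: {bad[:10]}")
    norm = np.linalg.norm(acc, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("degenerate vertex normal (incident normals cancel)")
    return acc / norm


def _cotangent_matrix(mesh: TriangleMesh, clamp: float = 1e4) -> sparse.csr_matrix:
    """Symmetric cotangent-weight matrix; cotangents clamped to +-clamp."""
    t = mesh.triangles
    p = mesh.vertices
    n = mesh.n_vertices
    i_list, j_list, w_list = [], [], []
    for k in range(3):
        # angle at vertex a is opposite edge (b, c)
        a, b, c = t[:, k], t[:, (k + 1) % 3], t[:, (k + 2) % 3]
        u = p[b] - p[a]
        v = p[c] - p[a]
        cos = np.einsum("ij,ij->i", u, v)
        sin = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.clip(cos / np.maximum(sin, 1e-300), -clamp, clamp)
        i_list += [b, c]
        j_list += [c, b]
        w_list += [cot, cot]
    i = np.concatenate(i_list)
    j = np.concatenate(j_list)
    w = 0.5 * np.concatenate(w_list)
    return sparse.csr_matrix((w, (i, j)), shape=(n, n))


def _mixed_voronoi_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex mixed Voronoi area: circumcentric cell for non-obtuse
    triangles, half/quarter triangle area at/opposite an obtuse corner."""
    t = mesh.triangles
    p = mesh.vertices
    areas = mesh.triangle_areas()
    corner_cos = np.empty((t.shape[0], 3))
    cot = np.empty((t.shape[0], 3))
    for k in range(3):
        a, b, c = t[:, k], t[:, (k + 1) % 3], t[:, (k + 2) % 3]
        u = p[b] - p[a]
        v = p[c] - p[a]
        cos = np.einsum("ij,ij->i", u, v)
        sin = np.linalg.norm(np.cross(u, v), axis=1)
        corner_cos[:, k] = cos
        cot[:, k] = cos / np.maximum(sin, 1e-300)
    edge_sq = np.empty((t.shape[0], 3))
    for k in range(3):
        b, c = t[:, (k + 1) % 3], t[:, (k + 2) % 3]
        edge_sq[:, k] = np.sum((p[b] - p[c]) ** 2, axis=1)  # opposite corner k
    obtuse_at = np.where(
        np.any(corner_cos < 0, axis=1), np.argmin(corner_cos, axis=1), -1
    )
    contrib = np.empty((t.shape[0], 3))
    non_obtuse = obtuse_at < 0
    # Voronoi: corner k gets (|e_j|^2 cot(j) + |e_i|^2 cot(i)) / 8
    for k in range(3):
        j, i = (k + 1) % 3, (k + 2) % 3
        contrib[:, k] = (edge_sq[:, j] * cot[:, j] + edge_sq[:, i] * cot[:, i]) / 8.0
    for k in range(3):
        rows = ~non_obtuse
        contrib[rows, k] = np.where(
            obtuse_at[rows] == k, areas[rows] / 2.0, areas[rows] / 4.0
        )
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, t[:, k], contrib[:, k])
    return out


def mean_curvature(mesh: TriangleMesh) -> ScalarField:
    """Discrete mean curvature (1/mm) via the cotangent Laplacian.

    The magnitude comes from the Laplace–Beltrami of the position function
    (mean-curvature normal); the sign from its projection on the vertex
    normal, so a sphere with outward normals has positive curvature.
    Boundary vertices are set to the missing sentinel (NaN): the one-ring
    there is open and the operator is biased.
    """
    W = _cotangent_matrix(mesh)
    area = _mixed_voronoi_areas(mesh)
    deg = np.asarray(W.sum(axis=1)).ravel()
    # mean curvature vector K_i = (1/(2A_i)) * sum_j w_ij (x_i - x_j)
    K = (deg[:, None] * mesh.vertices - W @ mesh.vertices) / (
        2.0 * np.maximum(area, 1e-300)[:, None]
    )
    # W carries (cot a + cot b)/2, so K . n is the mean curvature directly
    normals = vertex_normals(mesh)
    h = np.einsum("ij,ij->i", K, normals)
    h[mesh.boundary_vertices()] = np.nan
    return ScalarField(h, name="mean_curvature")


def geodesic_gaussian_smooth(
    field: ScalarField | np.ndarray,
    mesh: TriangleMesh,
    fwhm_mm: float,
) -> ScalarField:
    """Gaussian smoothing weighted by geodesic distance along the surface.

    value(v) = sum_u w(d_g(v,u)) x_u / sum_u w(d_g(v,u)),
    w(d) = exp(-d^2 / (2 sigma^2)), sigma = fwhm / 2.3548, support truncated
    at 3 sigma.  Masked (NaN) vertices are excluded from both sums and stay
    missing in the output.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if isinstance(field, ScalarField):
        x = field.values
        name = field.name
    else:
        x = np.asarray(field, dtype=np.float64)
        name = ""
    if x.shape[0] != mesh.n_vertices:
        raise ValueError("field length does not match vertex count")
    sigma = fwhm_mm / FWHM_TO_SIGMA
    D = dijkstra(mesh.adjacency_matrix(), directed=False, limit=3.0 * sigma)
    with np.errstate(invalid="ignore"):
        W = np.exp(-(D**2) / (2.0 * sigma**2))
    W[~np.isfinite(D)] = 0.0
    valid = np.isfinite(x)
    xz = np.where(valid, x, 0.0)
    num = W @ xz
    den = W @ valid.astype(np.float64)
    out = np.full_like(x, np.nan)
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return ScalarField(out, name=name)
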