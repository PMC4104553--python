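"""Local flattening of a surface patch by classical MDS of geodesics.

Two steps: (1) all-pairs graph-geodesic distances along mesh edges
(repeated single-source Dijkstra); (2) classical multidimensional scaling —
double-center -1/2 J D∘2 J, keep the top-2 eigenpairs, scale eigenvectors by
sqrt(eigenvalue).  For a developable patch the graph metric is (nearly) flat
and the embedding unrolls it isometrically; intrinsic curvature shows up as
embedding stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import linalg

from .mesh import TriangleMesh, pairwise_geodesic_distances

__all__ = ["FlatMap", "flatten_mds", "distortion_metrics", "procrustes_residual"]


@dataclass
class FlatMap:
    """2D embedding of a patch with its normalized stress."""

    coords2d: np.ndarray  # (n, 2) mm
    stress: float
    mesh_id: str = ""
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(2))
    eigenvalue_mass: float = np.nan  # retained / total positive eigenvalue mass

    def __post_init__(self):
        self.coords2d = np.asarray(self.coords2d, dtype=np.float64)
        if not np.all(np.isfinite(self.coords2d)):
            raise ValueError("flat coordinates must be finite")
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]


def _stress(flat_d: np.ndarray, geo_d: np.ndarray) -> float:
    iu = np.triu_indices_from(geo_d, k=1)
    num = np.sum((flat_d[iu] - geo_d[iu]) ** 2)
    den = np.sum(geo_d[iu] ** 2)
    return float(np.sqrt(num / den))


def flatten_mds(mesh: TriangleMesh) -> FlatMap:
    """Classical MDS of the graph-geodesic distance matrix, top-2 axes.

    Deterministic orientation: the first axis is aligned with increasing
    posterior→anterior (world y) coordinate, and the second axis is flipped
    if needed so the majority of triangles keep their winding (no mirror
    image).
    """
    n = mesh.n_vertices
    if n < 4:
        raise ValueError("need at least 4 vertices to flatten")
    D = pairwise_geodesic_distances(mesh)
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    w, V = linalg.eigh(B, subset_by_index=[n - 2, n - 1])
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if np.any(w <= 0):
        raise ValueError("fewer than 2 positive eigenvalues: degenerate geometry")
    coords = V * np.sqrt(w)
    # orientation: axis 0 along posterior->anterior
    y = mesh.vertices[:, 1]
    if np.corrcoef(coords[:, 0], y)[0, 1] < 0:
        coords[:, 0] *= -1
    # reflection: preserve the majority triangle winding
    t = mesh.triangles
    a, b, c = coords[t[:, 0]], coords[t[:, 1]], coords[t[:, 2]]
    signed = _cross2(b - a, c - a)
    if np.sum(signed > 0) < np.sum(signed < 0):
        coords[:, 1] *= -1
    w_all = linalg.eigvalsh(B)
    pos_mass = np.sum(w_all[w_all > 0])
    flat_d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    # calibrate the global scale to geodesic millimetres: the graph metric
    # systematically overestimates surface distance (shortest paths zig-zag
    # along edges), and the eigenvalue scaling inherits that inflation
    iu = np.triu_indices(n, k=1)
    s = np.sum(flat_d[iu] * D[iu]) / np.sum(flat_d[iu] ** 2)
    coords *= s
    flat_d *= s
    return FlatMap(
        coords2d=coords,
        stress=_stress(flat_d, D),
        eigenvalues=w,
        eigenvalue_mass=float(np.sum(w) / pos_mass),
    )


def distortion_metrics(
    mesh: TriangleMesh, flat: FlatMap
) -> Tuple[float, np.ndarray]:
    """(stress, per-triangle area ratio flat/3D)."""
    D = pairwise_geodesic_distances(mesh)
    c = flat.coords2d
    flat_d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    stress = _stress(flat_d, D)
    t = mesh.triangles
    a, b, cc = c[t[:, 0]], c[t[:, 1]], c[t[:, 2]]
    flat_area = 0.5 * np.abs(_cross2(b - a, cc - a))
    ratio = flat_area / mesh.triangle_areas()
    return stress, ratio


def procrustes_residual(x: np.ndarray, y: np.ndarray) -> float:
    """RMS residual (mm) after optimally rotating/reflecting/translating x
    onto y (no scaling): similarity-invariance diagnostic for flat maps."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(xc.T @ yc)
    r = u @ vt
    resid = xc @ r - yc
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
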