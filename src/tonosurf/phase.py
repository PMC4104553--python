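"""Phase decoding: cross-correlation between opposing sweep directions.

A vertex preferring ascending-tone index k responds at onset k*block_s
within the low-to-high cycle and at (n-1-k)*block_s within the high-to-low
cycle, so the lag of maximum cross-correlation between the two run types is
delta = (2k - (n-1)) * block_s.  The hemodynamic delay shifts both run types
equally and cancels.  Inverting delta gives the preferred tone; vertices are
kept only where the peak correlation exceeds a threshold (default 0.2,
strict).

Sign convention (fixed, also recorded in map metadata): the lag is the
shift applied to the second (high-to-low) series, r(l) = corr(a(t), b(t-l));
a positive lag means the low-to-high run's response occurs *later* in its
cycle than the high-to-low run's, i.e. a high preferred frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .design import SweepDesign
from .mesh import TriangleMesh, geodesic_gaussian_smooth
from .timeseries import SurfaceTimeSeries

__all__ = [
    "BestFrequencyMap",
    "xcorr_peak",
    "lag_to_index",
    "best_frequency_map",
    "iso_frequency_contours",
]


@dataclass
class BestFrequencyMap:
    """Decoded per-vertex frequency preference with its inclusion mask."""

    preferred_index: np.ndarray  # float; NaN where masked out
    preferred_hz: np.ndarray
    lag_s: np.ndarray
    peak_r: np.ndarray
    mask: np.ndarray
    threshold: float
    meta: Dict[str, str] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.preferred_index.shape[0]


def _lag_order(max_lag_samples: int) -> List[int]:
    """Lag candidates ordered for tie-breaking: smallest |l| first, negative
    before positive."""
    return sorted(range(-max_lag_samples, max_lag_samples + 1), key=lambda l: (abs(l), l))


def _overlap(a: np.ndarray, b: np.ndarray, lag: int):
    """Segments of a(t) and b(t - lag) over their common support (last axis)."""
    if lag >= 0:
        return a[..., lag:], b[..., : b.shape[-1] - lag]
    return a[..., :lag], b[..., -lag:]


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = np.einsum("...t,...t->...", xc, yc)
    den = np.sqrt(
        np.einsum("...t,...t->...", xc, xc) * np.einsum("...t,...t->...", yc, yc)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def xcorr_peak(
    a: np.ndarray, b: np.ndarray, tr_s: float, max_lag_s: float
) -> Tuple[float, float]:
    """Lag (s) and value of the maximum Pearson cross-correlation.

    r(l) is the correlation of the overlapping segments of a(t) and b(t-l)
    for integer sample lags l in [-L, L], L = round(max_lag_s / tr_s).
    Ties break toward the smallest |l|, then the negative lag.  Lags whose
    overlap has zero variance are skipped; if every lag is degenerate a
    ValueError is raised.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D signals")
    if a.size < 8:
        raise ValueError("need at least 8 samples")
    if max_lag_s >= a.size * tr_s / 2:
        raise ValueError("max_lag_s must be below half the series duration")
    L = int(round(max_lag_s / tr_s))
    best_lag, best_r = None, -np.inf
    for l in _lag_order(L):
        xa, xb = _overlap(a, b, l)
        r = _pearson_rows(xa, xb)
        if np.isnan(r):
            continue
        if r > best_r:
            best_lag, best_r = l, float(r)
    if best_lag is None:
        raise ValueError("all lags degenerate (zero-variance overlap)")
    return best_lag * tr_s, best_r


def lag_to_index(lag_s: float, design: SweepDesign) -> int:
    """Invert the peak lag to the ascending-frequency tone index.

    k = round(lag / (2*block_s) + (n-1)/2), clamped to [0, n-1]; clamping
    absorbs lag-quantization overshoot at the extremes.
    """
    n = design.n_tones
    k = int(round(lag_s / (2.0 * design.block_s) + (n - 1) / 2.0))
    return int(np.clip(k, 0, n - 1))


def best_frequency_map(
    lh: SurfaceTimeSeries,
    hl: SurfaceTimeSeries,
    design: SweepDesign,
    threshold: float = 0.2,
    max_lag_s: float = 16.8,
    strict: bool = True,
) -> BestFrequencyMap:
    """Decode the preferred frequency at every vertex.

    ``lh`` and ``hl`` are the conditioned (percent-change, band-passed)
    series of the low-to-high and high-to-low run types (averaged across
    runs of a direction).  The mask keeps vertices with peak correlation
    above ``threshold`` (strictly greater by default).  The lag search is
    linear (not circular): the 12 s pause breaks the cyclic ambiguity.
    """
    if lh.data.shape != hl.data.shape:
        raise ValueError("run types have mismatched shapes (different mesh?)")
    if lh.mesh_id != hl.mesh_id:
        raise ValueError("run types belong to different meshes")
    tr = lh.tr_s
    L = int(round(max_lag_s / tr))
    n_vert = lh.n_vertices
    best_r = np.full(n_vert, -np.inf)
    best_lag = np.zeros(n_vert, dtype=np.int64)
    any_valid = np.zeros(n_vert, dtype=bool)
    for l in _lag_order(L):
        xa, xb = _overlap(lh.data, hl.data, l)
        r = _pearson_rows(xa, xb)
        valid = np.isfinite(r)
        any_valid |= valid
        upd = valid & (r > best_r)
        best_r[upd] = r[upd]
        best_lag[upd] = l
    lag_s = best_lag * tr
    peak_r = np.where(any_valid, best_r, np.nan)
    with np.errstate(invalid="ignore"):
        mask = (peak_r > threshold) if strict else (peak_r >= threshold)
    mask &= any_valid
    freqs = design.frequencies_ascending
    n = design.n_tones
    k = np.clip(
        np.rint(lag_s / (2.0 * design.block_s) + (n - 1) / 2.0), 0, n - 1
    ).astype(np.int64)
    pref_idx = np.where(mask, k.astype(np.float64), np.nan)
    pref_hz = np.where(mask, freqs[k], np.nan)
    lag_out = np.where(any_valid, lag_s, np.nan)
    return BestFrequencyMap(
        preferred_index=pref_idx,
        preferred_hz=pref_hz,
        lag_s=lag_out,
        peak_r=peak_r,
        mask=mask,
        threshold=threshold,
        meta={
            "lag_convention": "shift applied to the high-to-low series; "
            "positive lag = low-to-high response later in cycle = high frequency",
            "max_lag_s": str(max_lag_s),
            "strict_threshold": str(strict),
        },
    )


# ---------------------------------------------------------------------------
# iso-frequency contours (marching triangles)
# ---------------------------------------------------------------------------

def _chain_segments(segments):
    """Join segments sharing edge keys into polylines (greedy walk)."""
    from collections import defaultdict

    adjacency = defaultdict(list)
    for si, (k1, k2, p1, p2) in enumerate(segments):
        adjacency[k1].append(si)
        adjacency[k2].append(si)
    used = [False] * len(segments)
    polylines = []
    for start in range(len(segments)):
        if used[start]:
            continue
        k1, k2, p1, p2 = segments[start]
        used[start] = True
        keys = [k1, k2]
        pts = [p1, p2]
        for end in (1, 0):
            while True:
                key = keys[-1] if end else keys[0]
                nxt = [s for s in adjacency[key] if not used[s]]
                if not nxt:
                    break
                si = nxt[0]
                used[si] = True
                a1, a2, q1, q2 = segments[si]
                nk, nq = (a2, q2) if a1 == key else (a1, q1)
                if end:
                    keys.append(nk)
                    pts.append(nq)
                else:
                    keys.insert(0, nk)
                    pts.insert(0, nq)
        polylines.append(np.asarray(pts))
    return polylines


def contour_lines(
    values: np.ndarray,
    coords: np.ndarray,
    triangles: np.ndarray,
    levels: Sequence[float],
) -> Dict[float, List[np.ndarray]]:
    """Marching-triangles level sets of a per-vertex field.

    Triangles touching a missing (NaN) vertex are skipped.  Returns, per
    level, a list of polylines (arrays of points in the coordinate space
    given, 2D or 3D); each polyline is closed or ends on the patch boundary.
    """
    values = np.asarray(values, dtype=np.float64)
    out: Dict[float, List[np.ndarray]] = {}
    ok_tri = ~np.any(np.isnan(values[triangles]), axis=1)
    tris = triangles[ok_tri]
    for level in levels:
        segments = []
        v = values[tris] - level
        for tri, dv in zip(tris, v):
            pts = []
            for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                a, b = dv[e0], dv[e1]
                if (a < 0 <= b) or (b < 0 <= a):
                    t = a / (a - b)
                    p = coords[tri[e0]] + t * (coords[tri[e1]] - coords[tri[e0]])
                    key = (min(tri[e0], tri[e1]), max(tri[e0], tri[e1]))
                    pts.append((key, p))
            if len(pts) == 2:
                segments.append((pts[0][0], pts[1][0], pts[0][1], pts[1][1]))
        out[level] = _chain_segments(segments) if segments else []
    return out


def iso_frequency_contours(
    bf_map: BestFrequencyMap,
    mesh: TriangleMesh,
    levels: Sequence[float],
    coords: np.ndarray | None = None,
    smooth_fwhm_mm: float = 1.0,
) -> Dict[float, List[np.ndarray]]:
    """Iso-frequency contours of the decoded index field.

    The integer preferred-index map is made real-valued by one pass of
    geodesic-Gaussian smoothing (integer fields give degenerate
    marching-triangle output), then contoured at the requested index
    levels.  ``coords`` selects the geometry (e.g. a flat map); defaults to
    the 3D mesh vertices.
    """
    field_vals = geodesic_gaussian_smooth(
        bf_map.preferred_index, mesh, smooth_fwhm_mm
    ).values
    if coords is None:
        coords = mesh.vertices
    return contour_lines(field_vals, np.asarray(coords), mesh.triangles, levels)
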