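"""Synthetic inputs: folded surface phantom with known tonotopy, simulated
phase-encoded BOLD runs, paired 4D volumes, and T1w/T2w structural phantoms.

The surface phantom is a developable sheet: a rectangle in parameters (u, v)
bent along u by a cylindrical fold (the circular-sulcus stand-in).  Bending
is applied through an arc-length parametrization, so the embedding is exactly
isometric to the parameter plane and graph geodesics are invariant to fold
depth.  The ground-truth frequency map is the high–low–high–low progression
along the posterior→anterior axis with reversals at u = -10, -3, +5 mm and a
non-responsive posterior strip (u < -12 mm).

Interior vertices are jittered and triangulated by Delaunay: an irregular
triangulation keeps the graph-geodesic metric isotropic (a regular lattice
over- estimates distances much more in some directions than others, which
would bias the MDS flattening).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial import Delaunay
from scipy.special import gammaln

from .design import LOW_TO_HIGH, SweepDesign
from .mesh import FWHM_TO_SIGMA, TriangleMesh
from .timeseries import SurfaceTimeSeries, VolumeImage

__all__ = [
    "GroundTruthMap",
    "SimulationParams",
    "make_stp_phantom",
    "hemodynamic_response",
    "simulate_bold",
    "rasterize_to_volume",
    "make_myelin_phantom",
    "make_probe_sheet",
    "grid_mesh",
]

#: Additive noise SD (% signal units) calibrated so that the decoded map's
#: median peak correlation sits near 0.4 when 4 runs per direction are
#: averaged on the default phantom (the mask-threshold regime of the method).
DEFAULT_NOISE_SD = 2.0

BASELINE = 100.0


@dataclass
class GroundTruthMap:
    """Per-vertex simulated frequency preference.

    ``preferred_index`` holds the tone index (0..n-1) or -1 for
    non-responsive vertices, which carry amplitude 0.
    """

    preferred_index: np.ndarray
    tuning_fwhm_idx: float
    amplitude: np.ndarray

    def __post_init__(self):
        self.preferred_index = np.asarray(self.preferred_index, dtype=np.int64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        if np.any(self.amplitude[self.preferred_index < 0] != 0):
            raise ValueError("non-responsive vertices must have amplitude 0")

    @property
    def responsive(self) -> np.ndarray:
        return self.preferred_index >= 0


@dataclass
class SimulationParams:
    """Noise and nuisance model for the BOLD simulator (% signal units)."""

    noise_sd: float = DEFAULT_NOISE_SD
    hemo_delay_s: float = 6.0
    hemo_undershoot_s: float = 16.0
    drift_amp: float = 1.0
    n_runs_per_direction: int = 1
    seed: int = 0
    noise_smooth_fwhm_mm: float = 0.0  # spatially correlated noise, off by default

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_runs_per_direction < 1:
            raise ValueError("n_runs_per_direction must be >= 1")


# ---------------------------------------------------------------------------
# surface phantom
# ---------------------------------------------------------------------------

_U_RANGE = (-15.0, 10.0)  # posterior -> anterior (y) extent, mm
_V_RANGE = (-6.0, 6.0)  # medio-lateral extent, mm
_FOLD_CENTER = -2.0  # fold location along u, mm
_FOLD_WIDTH = 3.0  # Gaussian half-width of the fold profile, mm
_REVERSALS_U = (-10.0, -3.0, 5.0, 10.0)
_REVERSALS_IDX = (8.0, 0.0, 8.0, 0.0)
_DEAD_STRIP_U = -12.0  # posterior non-responsive strip boundary


def _jittered_grid(n_u: int, n_v: int, rng: np.random.Generator):
    u = np.linspace(*_U_RANGE, n_u)
    v = np.linspace(*_V_RANGE, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    du = (u[1] - u[0]) * 0.35
    dv = (v[1] - v[0]) * 0.35
    ju = rng.uniform(-du, du, uu.shape)
    jv = rng.uniform(-dv, dv, vv.shape)
    # boundary vertices stay on the boundary (jitter along it only)
    ju[0, :] = ju[-1, :] = 0.0
    jv[:, 0] = jv[:, -1] = 0.0
    return (uu + ju).ravel(), (vv + jv).ravel()


def _fold_profile(fold_depth_mm: float):
    """Unit-speed profile curve (y(s), z(s)) of the cylindrical fold.

    Returns interpolators mapping arc length s to (y, z).  For depth 0 the
    map is the identity (y = s, z = 0).
    """
    t = np.linspace(_U_RANGE[0] - 8.0, _U_RANGE[1] + 8.0, 8001)
    z = -fold_depth_mm * np.exp(-((t - _FOLD_CENTER) ** 2) / (2.0 * _FOLD_WIDTH**2))
    dz = np.gradient(z, t)
    ds = np.sqrt(1.0 + dz**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t))])
    s -= np.interp(0.0, t, s)  # anchor s = 0 at t = 0
    return t, s, z


def _truth_from_u(u: np.ndarray, tuning_fwhm_idx: float, amplitude: float):
    idx_real = np.interp(u, _REVERSALS_U, _REVERSALS_IDX)
    idx = np.rint(idx_real).astype(np.int64)
    amp = np.full(u.shape, float(amplitude))
    dead = u < _DEAD_STRIP_U
    idx[dead] = -1
    amp[dead] = 0.0
    return GroundTruthMap(idx, tuning_fwhm_idx, amp)


def make_stp_phantom(
    n_u: int = 40,
    n_v: int = 40,
    fold_depth_mm: float = 3.0,
    seed: int = 0,
    tuning_fwhm_idx: float = 1.0,
    amplitude: float = 1.0,
) -> Tuple[TriangleMesh, GroundTruthMap]:
    """Folded superior-temporal-plane-like patch with ground-truth tonotopy.

    The u parameter (posterior→anterior, spanning [-15, +10] mm; equal to
    the world y coordinate when ``fold_depth_mm`` is 0) carries the
    high-low-high-low preferred-index progression; v spans 12 mm across.
    """
    if n_u < 10 or n_v < 10:
        raise ValueError("need n_u, n_v >= 10")
    rng = np.random.default_rng(seed)
    u, v = _jittered_grid(n_u, n_v, rng)
    tri = Delaunay(np.column_stack([u, v])).simplices
    # enforce counter-clockwise winding in the parameter plane (+z normals)
    p = np.column_stack([u, v])
    a, b, c = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    ab, ac = b - a, c - a
    cw = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0] < 0
    tri[cw] = tri[cw][:, ::-1]

    t_grid, s_grid, z_grid = _fold_profile(fold_depth_mm)
    y = np.interp(u, s_grid, t_grid)
    z = np.interp(y, t_grid, z_grid)
    vertices = np.column_stack([v, y, z])
    # float32 grid so GIFTI round-trips are bit-exact
    vertices = vertices.astype(np.float32).astype(np.float64)
    mesh = TriangleMesh(vertices, tri)
    truth = _truth_from_u(u, tuning_fwhm_idx, amplitude)
    return mesh, truth


# ---------------------------------------------------------------------------
# hemodynamics and BOLD
# ---------------------------------------------------------------------------

def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1.0) * np.log(tp) - tp - gammaln(shape))
    return out


def hemodynamic_response(
    t_s,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response, normalized to peak 1.

    Positive lobe peaking at ``peak_s``, undershoot peaking at
    ``undershoot_s`` with relative amplitude ``undershoot_ratio``; zero for
    t < 0.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=np.float64))
    g = _gamma_pdf(t, peak_s + 1.0) - undershoot_ratio * _gamma_pdf(
        t, undershoot_s + 1.0
    )
    ref = np.linspace(0.0, 40.0, 4001)
    gref = _gamma_pdf(ref, peak_s + 1.0) - undershoot_ratio * _gamma_pdf(
        ref, undershoot_s + 1.0
    )
    out = g / gref.max()
    return out if np.ndim(t_s) else float(out[0])


_FINE_DT = 0.1  # s; TR = 1.4 s is an exact multiple


def _tone_index_fine(design: SweepDesign, t: np.ndarray) -> np.ndarray:
    """Ascending-frequency tone index playing at each fine time, -1 if silent."""
    idx = np.full(t.shape, -1, dtype=np.int64)
    phase = np.mod(t, design.cycle_s)
    on = (t < design.stimulus_span_s) & (phase < design.sweep_s)
    pos = np.minimum((phase[on] / design.block_s).astype(np.int64), design.n_tones - 1)
    if design.direction == LOW_TO_HIGH:
        idx[on] = pos
    else:
        idx[on] = design.n_tones - 1 - pos
    return idx


def _response_templates(design: SweepDesign, truth: GroundTruthMap, params):
    """Noise-free % signal response sampled at TR, one row per tone index."""
    n_fine = int(round(design.n_volumes * design.tr_s / _FINE_DT))
    t = np.arange(n_fine) * _FINE_DT
    tone = _tone_index_fine(design, t)
    sigma_idx = truth.tuning_fwhm_idx / FWHM_TO_SIGMA
    kernel = hemodynamic_response(
        np.arange(0.0, 32.0, _FINE_DT), params.hemo_delay_s, params.hemo_undershoot_s
    )
    # scale so a single preferred-tone block evokes peak amplitude 1
    block = np.zeros(n_fine)
    block[: int(round(design.block_s / _FINE_DT))] = 1.0
    ref = np.convolve(block, kernel)[:n_fine]
    scale = 1.0 / ref.max()
    step = int(round(design.tr_s / _FINE_DT))
    sample = np.arange(design.n_volumes) * step
    out = np.empty((design.n_tones, design.n_volumes))
    for k in range(design.n_tones):
        drive = np.where(tone >= 0, np.exp(-((tone - k) ** 2) / (2 * sigma_idx**2)), 0.0)
        resp = np.convolve(drive, kernel)[:n_fine] * scale
        out[k] = resp[sample]
    return out


def simulate_bold(
    mesh: TriangleMesh,
    truth: GroundTruthMap,
    design: SweepDesign,
    params: SimulationParams,
) -> List[SurfaceTimeSeries]:
    """Simulated runs for one sweep direction (``params.n_runs_per_direction``).

    Per vertex: Gaussian tuning in tone-index space drives the preferred and
    neighboring tone blocks, convolved with the hemodynamic response, on a
    baseline of 100 with a linear drift and i.i.d. Gaussian noise.  Seeded
    and reproducible; the two directions draw independent noise.
    """
    if truth.preferred_index.shape[0] != mesh.n_vertices:
        raise ValueError("truth length does not match vertex count")
    if np.any(truth.preferred_index >= design.n_tones):
        raise ValueError("ground-truth tone index exceeds design tone count")
    templates = _response_templates(design, truth, params)
    n_t = design.n_volumes
    t = np.arange(n_t) * design.tr_s
    drift = params.drift_amp * (t / t[-1] - 0.5)
    resp = np.zeros((mesh.n_vertices, n_t))
    live = truth.responsive
    resp[live] = truth.amplitude[live, None] * templates[truth.preferred_index[live]]

    dir_code = 0 if design.direction == LOW_TO_HIGH else 1
    runs = []
    for r in range(params.n_runs_per_direction):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(dir_code, r))
        )
        noise = rng.standard_normal((mesh.n_vertices, n_t)) * params.noise_sd
        if params.noise_smooth_fwhm_mm > 0 and params.noise_sd > 0:
            noise = _smooth_noise(noise, mesh, params)
        data = BASELINE + resp + drift[None, :] + noise
        runs.append(
            SurfaceTimeSeries(
                data, tr_s=design.tr_s, run_label=f"{design.direction}:{r}"
            )
        )
    return runs


def _smooth_noise(noise, mesh, params):
    """Spatially correlated noise: geodesic-Gaussian mixing, rescaled to the
    nominal marginal SD."""
    from scipy.sparse.csgraph import dijkstra

    sigma = params.noise_smooth_fwhm_mm / FWHM_TO_SIGMA
    D = dijkstra(mesh.adjacency_matrix(), directed=False, limit=3.0 * sigma)
    W = np.exp(-(D**2) / (2.0 * sigma**2))
    W[~np.isfinite(D)] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    mixed = W @ noise
    sd = mixed.std(axis=1, keepdims=True)
    return mixed / np.maximum(sd, 1e-12) * params.noise_sd


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def rasterize_to_volume(
    mesh: TriangleMesh, series: SurfaceTimeSeries, voxel_mm: float
) -> VolumeImage:
    """Write each vertex's series into the voxel containing it (mean on
    collision); background 0."""
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    if series.n_timepoints == 0:
        raise ValueError("series has no time points")
    if series.n_vertices != mesh.n_vertices:
        raise ValueError("series length does not match vertex count")
    lo = mesh.vertices.min(axis=0) - voxel_mm
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo
    vox = np.rint((mesh.vertices - lo) / voxel_mm).astype(np.int64)
    shape = tuple(vox.max(axis=0) + 2)
    acc = np.zeros(shape + (series.n_timepoints,))
    cnt = np.zeros(shape)
    np.add.at(acc, tuple(vox.T), series.data)
    np.add.at(cnt, tuple(vox.T), 1.0)
    nz = cnt > 0
    acc[nz] /= cnt[nz][:, None]
    return VolumeImage(acc, affine, units="%signal")


def make_myelin_phantom(
    grid_shape: Tuple[int, int, int] = (40, 40, 24),
    voxel_mm: float = 0.5,
    core_box: Tuple[Tuple[float, float, float], Tuple[float, float, float]] = (
        (5.0, 5.0, 2.0),
        (15.0, 15.0, 10.0),
    ),
    vessel_fraction: float = 0.01,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> Tuple[VolumeImage, VolumeImage, VolumeImage]:
    """T1w and T2w volumes whose ratio is 1.0 background / 1.5 in the core
    box, with multiplicative Gaussian noise and blood-vessel spikes (ratio
    5.0) at a ``vessel_fraction`` of voxels.  Returns (t1w, t2w, core mask).
    """
    if not (0.0 <= vessel_fraction <= 0.05):
        raise ValueError("vessel_fraction must be within [0, 0.05]")
    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    idx = np.indices(grid_shape).reshape(3, -1).T
    world = idx * voxel_mm
    lo, hi = np.asarray(core_box[0]), np.asarray(core_box[1])
    core = np.all((world >= lo) & (world <= hi), axis=1).reshape(grid_shape)
    ratio = np.where(core, 1.5, 1.0)
    if noise_sd > 0:
        ratio = ratio * (1.0 + noise_sd * rng.standard_normal(grid_shape))
    n_vessel = int(round(vessel_fraction * ratio.size))
    if n_vessel:
        flat = rng.choice(ratio.size, size=n_vessel, replace=False)
        ratio.ravel()[flat] = 5.0
    t2w = VolumeImage(np.ones(grid_shape), affine, units="T2w")
    t1w = VolumeImage(ratio, affine, units="T1w")
    return t1w, t2w, VolumeImage(core.astype(np.float64), affine, units="core")


# ---------------------------------------------------------------------------
# simple meshes
# ---------------------------------------------------------------------------

def grid_mesh(
    x: np.ndarray, y: np.ndarray, z: float = 0.0
) -> TriangleMesh:
    """Regular rectangular grid in the z = const plane, CCW seen from +z."""
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    nx_, ny_ = len(x), len(y)
    tris = []
    for i in range(nx_ - 1):
        for j in range(ny_ - 1):
            a = i * ny_ + j
            b = (i + 1) * ny_ + j
            c = (i + 1) * ny_ + j + 1
            d = i * ny_ + j + 1
            tris.append([a, b, c])
            tris.append([a, c, d])
    return TriangleMesh(verts, np.asarray(tris))


def make_probe_sheet(
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
    z: float,
    spacing_mm: float,
) -> TriangleMesh:
    """Flat probe mesh at height z with +z normals, for depth sampling."""
    x = np.arange(x_range[0], x_range[1] + spacing_mm / 2, spacing_mm)
    y = np.arange(y_range[0], y_range[1] + spacing_mm / 2, spacing_mm)
    return grid_mesh(x, y, z)
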