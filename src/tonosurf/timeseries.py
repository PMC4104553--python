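"""Per-vertex BOLD signal conditioning and volume↔surface transfer.

Conditioning order matters: percent-signal-change is computed from the raw
(unfiltered) per-vertex mean first, then the zero-phase band-pass is applied.
A zero-phase band-pass drives the temporal mean to ~0, which would make
"percent of the mean" ill-defined if filtering came first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates

from .mesh import ScalarField, TriangleMesh

__all__ = [
    "SurfaceTimeSeries",
    "VolumeImage",
    "bandpass",
    "percent_signal_change",
    "average_runs",
    "project_volume_to_surface",
]


@dataclass
class SurfaceTimeSeries:
    """Vertex × time signal matrix sampled every ``tr_s`` seconds."""

    data: np.ndarray
    tr_s: float
    mesh_id: str = ""
    run_label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_vertices, n_timepoints)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def direction(self) -> str:
        """Sweep direction parsed from run_label ('<direction>:<run>')."""
        return self.run_label.split(":")[0]


@dataclass
class VolumeImage:
    """3D or 4D voxel grid with a voxel-to-world (RAS mm) affine; 4D last
    axis is time."""

    data: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError("volume must be 3D or 4D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points (n, 3)."""
        inv = np.linalg.inv(self.affine)
        p = np.asarray(points, dtype=np.float64)
        return p @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=np.float64)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


def bandpass(
    ts: SurfaceTimeSeries, low_hz: float = 0.02, high_hz: float = 0.1
) -> SurfaceTimeSeries:
    """Zero-phase 4th-order Butterworth band-pass along time.

    Applied forward-backward (``sosfiltfilt``) so no lag is introduced that
    would bias the cross-correlation stage.
    """
    nyq = 0.5 / ts.tr_s
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyq:.4g}) Hz"
        )
    sos = signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_s, output="sos"
    )
    out = signal.sosfiltfilt(sos, ts.data, axis=1)
    return replace(ts, data=out)


def percent_signal_change(ts: SurfaceTimeSeries) -> SurfaceTimeSeries:
    """x -> 100*(x - mean_v)/mean_v per vertex."""
    m = ts.data.mean(axis=1)
    bad = np.flatnonzero(np.abs(m) < 1e-12)
    if bad.size:
        raise ValueError(f"zero-mean vertices, cannot normalize: {bad[:20].tolist()}")
    out = 100.0 * (ts.data - m[:, None]) / m[:, None]
    return replace(ts, data=out)


def average_runs(
    runs: Sequence[SurfaceTimeSeries],
) -> Tuple[SurfaceTimeSeries, SurfaceTimeSeries]:
    """Elementwise mean and s.e.m. (SD/sqrt(n), SD with n-1 denominator)
    across runs of one direction."""
    if len(runs) < 1:
        raise ValueError("need at least one run")
    shape = runs[0].data.shape
    direction = runs[0].direction
    for r in runs[1:]:
        if r.data.shape != shape:
            raise ValueError("run shape mismatch")
        if r.direction != direction:
            raise ValueError("runs mix sweep directions")
    stack = np.stack([r.data for r in runs])
    mean = stack.mean(axis=0)
    n = len(runs)
    if n == 1:
        sem = np.full(shape, np.nan)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    label = f"{direction}:mean_of_{n}"
    out_mean = replace(runs[0], data=mean, run_label=label)
    out_sem = replace(runs[0], data=sem, run_label=f"{direction}:sem_of_{n}")
    return out_mean, out_sem


def _check_inside(vox: np.ndarray, shape: Sequence[int]) -> None:
    eps = 1e-9
    for ax in range(3):
        bad = np.flatnonzero((vox[:, ax] < -eps) | (vox[:, ax] > shape[ax] - 1 + eps))
        if bad.size:
            raise ValueError(
                f"vertex {int(bad[0])} falls outside the volume grid "
                f"(axis {ax}, voxel coord {vox[bad[0], ax]:.3f})"
            )


def project_volume_to_surface(vol: VolumeImage, mesh: TriangleMesh):
    """Trilinear interpolation of voxel values at each vertex's world position.

    Returns a :class:`ScalarField` for a 3D volume or a
    :class:`SurfaceTimeSeries` (tr_s left at 1.0; caller overrides) for 4D.
    """
    vox = vol.world_to_voxel(mesh.vertices)
    _check_inside(vox, vol.data.shape[:3])
    coords = np.clip(vox.T, 0, np.array(vol.data.shape[:3])[:, None] - 1.0)
    if not vol.is_4d:
        vals = map_coordinates(vol.data, coords, order=1, mode="nearest")
        return ScalarField(vals, name=vol.units or "projected")
    n_t = vol.data.shape[3]
    out = np.empty((mesh.n_vertices, n_t))
    for t in range(n_t):
        out[:, t] = map_coordinates(vol.data[..., t], coords, order=1, mode="nearest")
    return SurfaceTimeSeries(out, tr_s=1.0, run_label="projected:0")
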