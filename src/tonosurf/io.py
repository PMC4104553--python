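"""GIFTI / NIfTI file I/O and plain-text configuration.

Surfaces go to ``.surf.gii`` (POINTSET + TRIANGLE), per-vertex maps and
time series to ``.func.gii``/``.shape.gii`` (one data array per map/time
point), volumes to ``.nii``/``.nii.gz``.  Coordinates are RAS millimetres.
Every writer stamps provenance metadata (config hash, seed) when given.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List

import nibabel as nib
import numpy as np
from nibabel import gifti

from .mesh import ScalarField, TriangleMesh
from .timeseries import SurfaceTimeSeries, VolumeImage

__all__ = [
    "write_gifti_mesh",
    "read_gifti_mesh",
    "write_gifti_metric",
    "read_gifti_metric",
    "read_scalar_field",
    "read_surface_timeseries",
    "write_nifti",
    "read_nifti",
    "write_contours",
    "PipelineConfig",
    "parse_config",
    "config_hash",
]


def _meta(provenance: Dict[str, str] | None) -> gifti.GiftiMetaData:
    md = gifti.GiftiMetaData()
    for k, v in (provenance or {}).items():
        md[k] = str(v)
    return md


def write_gifti_mesh(
    path, mesh: TriangleMesh, provenance: Dict[str, str] | None = None
) -> None:
    img = gifti.GiftiImage(meta=_meta(provenance))
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32),
            intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32),
            intent="NIFTI_INTENT_TRIANGLE",
            datatype="NIFTI_TYPE_INT32",
        )
    )
    nib.save(img, str(path))


def read_gifti_mesh(path) -> TriangleMesh:
    img = nib.load(str(path))
    pts = [d for d in img.darrays if d.intent == 1008]  # POINTSET
    tri = [d for d in img.darrays if d.intent == 1009]  # TRIANGLE
    if not pts or not tri:
        raise ValueError(f"{path}: missing POINTSET or TRIANGLE data array")
    return TriangleMesh(pts[0].data.astype(np.float64), tri[0].data.astype(np.int64))


def write_gifti_metric(
    path,
    data: np.ndarray | ScalarField,
    names: List[str] | None = None,
    provenance: Dict[str, str] | None = None,
) -> None:
    """Per-vertex map(s): 1-D array/ScalarField or (n_vertices, n_maps)."""
    if isinstance(data, ScalarField):
        names = names or ([data.name] if data.name else None)
        data = data.values
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr[:, None]
    img = gifti.GiftiImage(meta=_meta(provenance))
    for j in range(arr.shape[1]):
        da = gifti.GiftiDataArray(
            np.ascontiguousarray(arr[:, j]),
            intent="NIFTI_INTENT_NONE",
            datatype="NIFTI_TYPE_FLOAT32",
        )
        if names and j < len(names):
            da.meta["Name"] = names[j]
        img.add_gifti_data_array(da)
    nib.save(img, str(path))


def read_gifti_metric(path, mesh: TriangleMesh | None = None) -> np.ndarray:
    """(n_vertices, n_maps) float array; validates vertex count if a mesh
    is given."""
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"{path}: no data arrays")
    arr = np.column_stack([d.data.astype(np.float64) for d in img.darrays])
    if mesh is not None and arr.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"{path}: metric has {arr.shape[0]} vertices, mesh has {mesh.n_vertices}"
        )
    return arr


def read_scalar_field(path, mesh: TriangleMesh | None = None) -> ScalarField:
    arr = read_gifti_metric(path, mesh)
    return ScalarField(arr[:, 0], name=Path(str(path)).stem)


def read_surface_timeseries(
    path, tr_s: float, mesh: TriangleMesh | None = None, run_label: str = ""
) -> SurfaceTimeSeries:
    arr = read_gifti_metric(path, mesh)
    return SurfaceTimeSeries(arr, tr_s=tr_s, run_label=run_label)


def write_nifti(
    path, vol: VolumeImage, provenance: Dict[str, str] | None = None
) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    if provenance:
        img.header["descrip"] = ";".join(
            f"{k}={v}" for k, v in provenance.items()
        )[:79].encode()
    nib.save(img, str(path))


def read_nifti(path) -> VolumeImage:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=np.float64)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")
    return VolumeImage(data, affine)


def write_contours(path, contours: Dict[float, List[np.ndarray]]) -> None:
    """Plain-text polylines: '# level <x>' then one 'x y [z]' line per point,
    blank line between polylines."""
    with open(path, "w") as fh:
        for level in sorted(contours):
            for line in contours[level]:
                fh.write(f"# level {level}\n")
                for p in line:
                    fh.write(" ".join(f"{c:.6f}" for c in p) + "\n")
                fh.write("\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable parameters of the two pipelines, overridable from a
    plain-text key=value file and CLI flags."""

    # sweep design
    f_start_hz: float = 500.0
    n_tones: int = 9
    block_s: float = 2.0
    pause_s: float = 12.0
    n_cycles: int = 15
    tr_s: float = 1.4
    n_volumes: int = 343
    # conditioning / decoding
    low_hz: float = 0.02
    high_hz: float = 0.1
    no_filter: bool = False
    threshold: float = 0.2
    max_lag_s: float = 16.8
    contour_fwhm_mm: float = 1.0
    # myelin
    max_depth_mm: float = 2.0
    step_mm: float = 0.25
    myelin_fwhm_mm: float = 1.0
    per_vertex_sd: bool = False
    # simulation
    n_u: int = 40
    n_v: int = 40
    fold_depth_mm: float = 3.0
    noise_sd: float = -1.0  # <0 -> simulator default
    n_runs_per_direction: int = 1
    hemo_delay_s: float = 6.0
    drift_amp: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.threshold < -1 or self.threshold > 1:
            raise ValueError("threshold must be a correlation value")
        if self.block_s <= 0 or self.tr_s <= 0 or self.n_tones < 1:
            raise ValueError("invalid design parameters")
        if self.max_depth_mm <= 0 or self.step_mm <= 0:
            raise ValueError("invalid depth-sampling parameters")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def parse_config(text: str, base: PipelineConfig | None = None) -> PipelineConfig:
    """Parse key=value lines ('#' comments); unknown keys are rejected."""
    values = asdict(base) if base is not None else asdict(PipelineConfig())
    types = {f.name: f.type for f in fields(PipelineConfig)}
    py_types = {f.name: type(getattr(PipelineConfig(), f.name)) for f in fields(PipelineConfig)}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {ln}: expected key=value, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in values:
            raise ValueError(f"config line {ln}: unknown key {key!r}")
        t = py_types[key]
        if t is bool:
            if val.lower() not in _BOOL:
                raise ValueError(f"config line {ln}: bad boolean {val!r}")
            values[key] = _BOOL[val.lower()]
        else:
            values[key] = t(val)
    return PipelineConfig(**values)


def config_hash(config: PipelineConfig) -> str:
    blob = ";".join(f"{k}={v}" for k, v in sorted(asdict(config).items()))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
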