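#!/usr/bin/env python
"""Surface myelin index on the structural phantom: T1w/T2w ratio sampled
across cortical depth, global +-1 SD exclusion (removes vessel spikes),
1 mm geodesic smoothing; quantifies core-vs-background contrast."""

import csv
from pathlib import Path

import numpy as np

from tonosurf.io import write_gifti_metric
from tonosurf.myelin import myelin_map, ratio_volume, sample_depth
from tonosurf.simulate import make_myelin_phantom, make_probe_sheet

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    t1w, t2w, _ = make_myelin_phantom(vessel_fraction=0.01, seed=1)
    mesh = make_probe_sheet((1.5, 18.5), (1.5, 18.5), 4.0, 0.5)
    m = myelin_map(t1w, t2w, mesh).values
    v = mesh.vertices
    core = (v[:, 0] >= 6) & (v[:, 0] <= 14) & (v[:, 1] >= 6) & (v[:, 1] <= 14)
    outside = (v[:, 0] <= 4) | (v[:, 0] >= 16) | (v[:, 1] <= 4) | (v[:, 1] >= 16)
    samples = sample_depth(ratio_volume(t1w, t2w), mesh)
    gm, gs = float(np.nanmean(samples.values)), float(np.nanstd(samples.values))
    print(
        f"myelin index: core mean {np.nanmean(m[core]):.3f}, "
        f"background mean {np.nanmean(m[outside]):.3f} "
        f"(injected 1.5 vs 1.0, 1% vessel spikes at 5.0)"
    )
    print(
        f"global depth-sample band m+-s = {gm:.3f} +- {gs:.3f}; "
        f"map maximum {np.nanmax(m):.3f} (spikes excluded)"
    )
    out = ROOT / "study"
    out.mkdir(parents=True, exist_ok=True)
    write_gifti_metric(out / "myelin.func.gii", m, ["myelin_index"])
    with open(ROOT / "myelin_contrast.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["core_mean", "background_mean", "global_mean", "global_sd", "map_max"])
        w.writerow(
            [
                round(float(np.nanmean(m[core])), 4),
                round(float(np.nanmean(m[outside])), 4),
                round(gm, 4),
                round(gs, 4),
                round(float(np.nanmax(m)), 4),
            ]
        )
    print(f"map -> {out / 'myelin.func.gii'}; table -> {ROOT / 'myelin_contrast.csv'}")
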