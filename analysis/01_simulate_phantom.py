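#!/usr/bin/env python
"""Generate the synthetic study: folded STP-like surface phantom with
ground-truth tonotopy, phase-encoded BOLD runs for both sweep directions
(4 runs each at the calibrated noise level), and T1w/T2w structural
phantoms.  Everything downstream (02-05) reads from results/study/."""

from pathlib import Path

from tonosurf.cli import run_pipeline
from tonosurf.io import PipelineConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "study"

if __name__ == "__main__":
    cfg = PipelineConfig(n_u=40, n_v=40, fold_depth_mm=3.0, n_runs_per_direction=4, seed=1)
    res = run_pipeline(cfg, "simulate", OUT)
    print(f"wrote {len(res.outputs)} files to {OUT}")
    print(f"phantom vertices: {int(res.qc['n_vertices'])}")
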