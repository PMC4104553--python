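"""Phase-encoded sweep stimulus schedule and derived regressors.

One cycle presents every tone of a half-octave series in 2 s blocks
(18 s of sound for 9 tones) followed by a 12 s silent pause; the 30 s
cycle repeats 15 times per run, in ascending (low-to-high) or descending
(high-to-low) frequency order.  Volumes are sampled every TR = 1.4 s,
343 per run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "SweepDesign",
    "half_octave_series",
    "tone_onsets",
    "on_block_regressor",
    "default_design",
    "epi_count",
    "voxel_volume_mm3",
]

LOW_TO_HIGH = "low_to_high"
HIGH_TO_LOW = "high_to_low"


@dataclass(frozen=True)
class SweepDesign:
    """The phase-encoded stimulus schedule for one run type.

    ``frequencies_hz`` is stored in *presentation* order, i.e. strictly
    increasing for a low-to-high run and strictly decreasing for a
    high-to-low run.
    """

    frequencies_hz: Tuple[float, ...]
    block_s: float = 2.0
    pause_s: float = 12.0
    n_cycles: int = 15
    tr_s: float = 1.4
    direction: str = LOW_TO_HIGH
    n_volumes: int = 343

    def __post_init__(self):
        object.__setattr__(
            self, "frequencies_hz", tuple(float(f) for f in self.frequencies_hz)
        )
        f = np.asarray(self.frequencies_hz)
        if f.size < 1:
            raise ValueError("need at least one tone")
        if self.direction not in (LOW_TO_HIGH, HIGH_TO_LOW):
            raise ValueError(f"unknown direction {self.direction!r}")
        d = np.diff(f)
        if self.direction == LOW_TO_HIGH and not np.all(d > 0):
            raise ValueError("low_to_high frequencies must be strictly increasing")
        if self.direction == HIGH_TO_LOW and not np.all(d < 0):
            raise ValueError("high_to_low frequencies must be strictly decreasing")
        if self.block_s <= 0 or self.pause_s < 0 or self.tr_s <= 0:
            raise ValueError("timing parameters must be positive")
        if self.n_volumes * self.tr_s < self.n_cycles * self.cycle_s:
            raise ValueError("run shorter than the stimulus schedule")

    @property
    def n_tones(self) -> int:
        return len(self.frequencies_hz)

    @property
    def sweep_s(self) -> float:
        """Duration of the tone sweep within one cycle (s)."""
        return self.n_tones * self.block_s

    @property
    def cycle_s(self) -> float:
        return self.sweep_s + self.pause_s

    @property
    def stimulus_span_s(self) -> float:
        return self.n_cycles * self.cycle_s

    @property
    def frequencies_ascending(self) -> np.ndarray:
        return np.sort(np.asarray(self.frequencies_hz))

    def reversed(self) -> "SweepDesign":
        """The same schedule swept in the opposite direction."""
        other = HIGH_TO_LOW if self.direction == LOW_TO_HIGH else LOW_TO_HIGH
        return replace(
            self, frequencies_hz=tuple(reversed(self.frequencies_hz)), direction=other
        )


def half_octave_series(f_start_hz: float, n: int) -> np.ndarray:
    """Tones at half-octave steps: round(f_start * 2**(k/2)), k = 0..n-1."""
    if f_start_hz <= 0:
        raise ValueError("f_start_hz must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    return np.rint(f_start_hz * 2.0 ** (k / 2.0)).astype(np.int64)


def default_design(direction: str = LOW_TO_HIGH) -> SweepDesign:
    """The study schedule: 500–8000 Hz half-octave, 2 s blocks, 12 s pause,
    15 cycles of 30 s, TR 1.4 s, 343 volumes."""
    freqs = half_octave_series(500.0, 9).astype(float)
    if direction == HIGH_TO_LOW:
        freqs = freqs[::-1]
    return SweepDesign(frequencies_hz=tuple(freqs), direction=direction)


def tone_onsets(design: SweepDesign) -> np.ndarray:
    """Onset time (s) within a cycle of tone k, k indexing *ascending* frequency.

    Low-to-high: onset(k) = k*block_s.  High-to-low: onset(k) =
    (n-1-k)*block_s.  The silent pause occupies [n*block_s, cycle_s).
    """
    k = np.arange(design.n_tones)
    if design.direction == LOW_TO_HIGH:
        return k * design.block_s
    return (design.n_tones - 1 - k) * design.block_s


def on_block_regressor(design: SweepDesign) -> np.ndarray:
    """Boxcar over n_volumes samples: 1 during tone blocks, 0 in pauses and
    after the last cycle."""
    t = np.arange(design.n_volumes) * design.tr_s
    in_run = t < design.stimulus_span_s
    in_sweep = np.mod(t, design.cycle_s) < design.sweep_s
    return (in_run & in_sweep).astype(np.float64)


def epi_count(n_runs: int, design: SweepDesign | None = None) -> int:
    """Total EPI volumes over an acquisition of n_runs runs."""
    n_vol = design.n_volumes if design is not None else 343
    return int(n_runs) * int(n_vol)


def voxel_volume_mm3(in_plane_mm: float = 1.2, slice_mm: float = 1.2) -> float:
    """EPI voxel volume from in-plane resolution and slice thickness."""
    return in_plane_mm * in_plane_mm * slice_mm
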