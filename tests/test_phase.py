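import numpy as np
import pytest

from tonosurf.design import default_design
from tonosurf.mesh import geodesic_gaussian_smooth
from tonosurf.phase import (
    best_frequency_map,
    contour_lines,
    iso_frequency_contours,
    lag_to_index,
    xcorr_peak,
)
from tonosurf.simulate import SimulationParams, grid_mesh, simulate_bold
from tonosurf.timeseries import bandpass, percent_signal_change

TR = 1.4


def conditioned_pair(mesh, truth, params):
    lh = simulate_bold(mesh, truth, default_design("low_to_high"), params)[0]
    hl = simulate_bold(mesh, truth, default_design("high_to_low"), params)[0]
    return (
        bandpass(percent_signal_change(lh)),
        bandpass(percent_signal_change(hl)),
    )


class TestXcorrPeak:
    def test_identical_signals(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        lag, r = xcorr_peak(a, a, TR, 10 * TR)
        assert lag == 0.0
        assert r == pytest.approx(1.0)

    def test_delayed_copy_sign_convention(self):
        """b(t) = a(t-3dt) (a leads, b's events occur later): r(l) correlates
        a(t) with b(t-l), so the peak sits at l = -3 samples — a's events
        occur *earlier* than b's, and negative lag encodes that."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=120)
        b = np.roll(a, 3)  # b delayed by 3 samples
        b[:3] = 0.0
        lag, r = xcorr_peak(a, b, TR, 8 * TR)
        assert lag == pytest.approx(-3 * TR)
        assert r > 0.9

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        L = 10
        best = (-np.inf, None)
        for l in sorted(range(-L, L + 1), key=lambda l: (abs(l), l)):
            if l >= 0:
                xa, xb = a[l:], b[: len(b) - l]
            else:
                xa, xb = a[:l], b[-l:]
            r = np.corrcoef(xa, xb)[0, 1]
            if r > best[0]:
                best = (r, l)
        lag, r = xcorr_peak(a, b, TR, L * TR)
        assert lag == pytest.approx(best[1] * TR)
        assert r == pytest.approx(best[0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=90)
        b = rng.normal(size=90)
        lag_ab, r_ab = xcorr_peak(a, b, TR, 6 * TR)
        lag_ba, r_ba = xcorr_peak(b, a, TR, 6 * TR)
        assert lag_ab == pytest.approx(-lag_ba)
        assert r_ab == pytest.approx(r_ba)

    def test_degenerate_input_rejected(self):
        a = np.ones(50)
        with pytest.raises(ValueError, match="degenerate"):
            xcorr_peak(a, a, TR, 5 * TR)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            xcorr_peak(np.ones(4), np.ones(4), TR, TR)


class TestLagToIndex:
    def test_zero_lag_is_midband(self):
        d = default_design()
        assert lag_to_index(0.0, d) == 4
        assert d.frequencies_ascending[4] == 2000

    def test_extremes(self):
        d = default_design()
        assert lag_to_index(-16.0, d) == 0
        assert lag_to_index(16.0, d) == 8

    def test_intermediate(self):
        # round(3/4 + 4) = 5 -> 2828 Hz
        d = default_design()
        assert lag_to_index(3.0, d) == 5
        assert d.frequencies_ascending[5] == 2828

    def test_clamped_beyond_extremes(self):
        d = default_design()
        assert lag_to_index(-25.0, d) == 0
        assert lag_to_index(25.0, d) == 8


class TestBestFrequencyMap:
    def test_noiseless_recovery(self, small_phantom):
        mesh, truth = small_phantom
        lh, hl = conditioned_pair(
            mesh, truth, SimulationParams(noise_sd=0.0, drift_amp=0.0)
        )
        bf = best_frequency_map(lh, hl, default_design())
        resp = truth.responsive
        assert np.all(bf.mask[resp])
        assert np.array_equal(bf.preferred_index[resp], truth.preferred_index[resp])
        assert not np.any(bf.mask[~resp])
        assert np.all(np.isnan(bf.preferred_index[~resp]))

    def test_threshold_is_strict(self, small_phantom):
        mesh, truth = small_phantom
        lh, hl = conditioned_pair(
            mesh, truth, SimulationParams(noise_sd=2.0, drift_amp=0.0, seed=2)
        )
        bf = best_frequency_map(lh, hl, default_design())
        v = int(np.flatnonzero(truth.responsive)[0])
        at_value = best_frequency_map(
            lh, hl, default_design(), threshold=float(bf.peak_r[v])
        )
        assert not at_value.mask[v]
        non_strict = best_frequency_map(
            lh, hl, default_design(), threshold=float(bf.peak_r[v]), strict=False
        )
        assert non_strict.mask[v]

    def test_invariant_to_per_vertex_rescaling(self, small_phantom):
        mesh, truth = small_phantom
        lh, hl = conditioned_pair(
            mesh, truth, SimulationParams(noise_sd=1.0, drift_amp=0.0, seed=3)
        )
        bf = best_frequency_map(lh, hl, default_design())
        rng = np.random.default_rng(0)
        scale = rng.uniform(0.5, 2.0, (mesh.n_vertices, 1))
        lh.data = lh.data * scale + 5.0
        hl.data = hl.data * scale - 2.0
        bf2 = best_frequency_map(lh, hl, default_design())
        assert np.array_equal(
            np.nan_to_num(bf.preferred_index, nan=-1),
            np.nan_to_num(bf2.preferred_index, nan=-1),
        )
        assert np.allclose(bf.peak_r, bf2.peak_r, atol=1e-9)

    def test_shape_mismatch_rejected(self, small_phantom):
        mesh, truth = small_phantom
        lh, hl = conditioned_pair(
            mesh, truth, SimulationParams(noise_sd=0.0, drift_amp=0.0)
        )
        hl.data = hl.data[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            best_frequency_map(lh, hl, default_design())


class TestContours:
    def test_linear_field_gives_straight_line(self):
        mesh = grid_mesh(np.linspace(0, 4, 9), np.linspace(0, 2, 5))
        field = mesh.vertices[:, 0]  # linear in x
        cont = contour_lines(field, mesh.vertices[:, :2], mesh.triangles, [2.0])
        lines = cont[2.0]
        assert len(lines) == 1
        pts = lines[0]
        assert np.allclose(pts[:, 0], 2.0, atol=1e-6)
        # spans the full y extent of the patch
        assert pts[:, 1].min() == pytest.approx(0.0, abs=1e-6)
        assert pts[:, 1].max() == pytest.approx(2.0, abs=1e-6)

    def test_level_below_minimum_is_empty(self):
        mesh = grid_mesh(np.linspace(0, 4, 5), np.linspace(0, 2, 3))
        cont = contour_lines(
            mesh.vertices[:, 0], mesh.vertices[:, :2], mesh.triangles, [-1.0]
        )
        assert cont[-1.0] == []

    def test_phantom_reversals_give_multiple_contours(self, small_phantom):
        """The high-low-high-low gradient crosses index 4 on each limb."""
        mesh, truth = small_phantom
        field = np.where(
            truth.responsive, truth.preferred_index.astype(float), np.nan
        )
        smooth = geodesic_gaussian_smooth(field, mesh, 1.0).values
        cont = contour_lines(smooth, mesh.vertices, mesh.triangles, [4.0])
        assert len(cont[4.0]) >= 2

    def test_iso_frequency_contours_from_map(self, small_phantom):
        mesh, truth = small_phantom
        lh, hl = conditioned_pair(
            mesh, truth, SimulationParams(noise_sd=0.0, drift_amp=0.0)
        )
        bf = best_frequency_map(lh, hl, default_design())
        cont = iso_frequency_contours(bf, mesh, levels=[4.0])
        assert len(cont[4.0]) >= 2


class TestHemodynamicDelayInvariance:
    def test_decoded_map_independent_of_delay(self, small_phantom):
        mesh, truth = small_phantom
        maps = []
        for peak in (4.0, 7.0):
            lh, hl = conditioned_pair(
                mesh,
                truth,
                SimulationParams(noise_sd=0.0, drift_amp=0.0, hemo_delay_s=peak),
            )
            maps.append(best_frequency_map(lh, hl, default_design()))
        a, b = maps
        assert np.array_equal(
            np.nan_to_num(a.preferred_index, nan=-1),
            np.nan_to_num(b.preferred_index, nan=-1),
        )
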