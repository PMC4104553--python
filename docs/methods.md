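# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic phantoms do and do not show
about real data.

## Stimulus model

A sweep design is a half-octave tone series (default 500–8000 Hz, 9 tones,
`round(f0·2^(k/2))`), presented in 2 s constant-frequency blocks followed by
a 12 s silent pause; the 30 s cycle repeats 15 times (450 s of stimulation
inside a 343-volume run at TR 1.4 s). Tone-burst micro-timing inside a
block (50/200 ms bursts) is far below fMRI temporal resolution and is not
modeled: a block is a constant-frequency epoch. The two run types traverse
the series in opposite orders; their onset schedules are exact mirror
images, `onset_LH(k) + onset_HL(k) = 16 s`.

## Surface phantom

The phantom is a rectangle in parameters (u, v), u spanning the
posterior→anterior axis −15…+10 mm and v 12 mm across, bent along u by a
Gaussian-profile cylindrical fold (default depth 3 mm, half-width 3 mm,
centered at u = −2 mm). Bending goes through an arc-length
reparametrization of the profile curve, so the embedding is exactly
isometric to the parameter plane; at fold depth 0 the world y coordinate
equals u. The ground-truth preferred tone index is piecewise linear in u —
index 8 at u = −10, 0 at −3, 8 at +5, 0 at +10, constant in v — and the
strip u < −12 mm is non-responsive (amplitude 0). Interior grid points are
jittered (±0.35 of the spacing, seeded) and triangulated by Delaunay:
a regular lattice's graph geodesics overestimate off-axis distances by up
to ~8% in preferred directions, which would imprint lattice anisotropy on
the MDS flattening; an irregular triangulation makes the stretch isotropic
so it cancels in the embedding up to a global scale. Note that graph
geodesics on *any* triangulation carry a few-percent metrication error for
near-diagonal vertex pairs; only statements robust to that (fold
invariance, d²-weighted stress) are asserted.

## BOLD simulator

Per vertex, neural drive at fine time resolution (0.1 s) is a Gaussian
tuning curve in tone-index space, width FWHM 1.0 index by default so
adjacent tones evoke partial responses (needed for smooth lag maps),
evaluated at the tone playing at each instant and zero in the pause. The
drive is convolved with a double-gamma hemodynamic response (positive lobe
peaking at 6 s, undershoot at 16 s, ratio 1/6, peak normalized to 1) and
scaled so one preferred-tone block evokes a peak response of `amplitude`
(default 1, in percent-signal units), then sampled at TR on a baseline of
100 with a linear drift (default 1% over the run, exercising the high-pass
side of the filter) and i.i.d. Gaussian noise. Noise is seeded per
(direction, run) through `SeedSequence` spawn keys, so the two run types
draw independent noise and every run is reproducible. A spatially
correlated noise option (geodesic Gaussian mixing) exists for sensitivity
work and is off by default; the surface analyses never depend on it.

**Noise calibration.** The default `noise_sd = 2.0` (% signal) was fixed
once by a sweep: with 4 runs per direction averaged on the 40×40 phantom it
puts the median peak cross-correlation of responsive vertices at ≈ 0.40,
the regime in which the 0.2 inclusion mask is actually doing work. At that
operating point the decoder places ~86% of mapped responsive vertices
within ±1 tone index, and the 0.2 threshold excludes ~55–64% of
non-responsive (pure noise) vertices. The latter is a property of the
method, not of the noise level: a Pearson correlation of two independent
0.02–0.1 Hz band-limited series of 480 s has ≈ 2·B·T ≈ 77 effective degrees
of freedom (null SD ≈ 0.11), and maximizing over ±12 lags pushes the null
peak above 0.2 with probability ≈ 0.4 — at any noise amplitude, since
correlation is scale-invariant. A markedly higher specificity at threshold
0.2 would require longer runs or a wider band, not a different simulator.

**What the phantom does not emulate:** EPI distortion, motion,
physiological noise spectra, vascular weighting, and the spatial
autocorrelation of real BOLD data. Recovery percentages on the phantom
therefore characterize the decoder under known, favorable conditions; they
are not fidelity claims about in-vivo data.

## Conditioning and decoding

Percent signal change uses the raw per-vertex temporal mean; the band-pass
(4th-order Butterworth, 0.02–0.1 Hz) is applied afterwards,
forward-backward so it is zero-phase and adds no lag bias. The order
matters: a zero-phase band-pass drives the temporal mean to ~0, which
would make "percent of the mean" ill-defined the other way round.

Cross-correlation is linear (not circular; the 12 s pause breaks the
periodic ambiguity between lags −16 and +14 s) over integer sample lags in
±16.8 s (±12 samples), one sample beyond the analytic extreme ±16 s. The
sign convention is fixed and stored in the map metadata: r(ℓ) correlates
the low-to-high series a(t) with the shifted high-to-low series b(t−ℓ), so
positive lag means a's response occurs later in its cycle, i.e. a high
preferred frequency. Ties break toward the smallest |ℓ|, then the negative
lag. Lags with zero-variance overlap are skipped; a vertex degenerate at
every lag (e.g. exactly silent input) is masked out. The lag→index
inverse clamps to [0, 8], absorbing the one-sample overshoot; because the
lag grid (1.4 s) is finer than half the index spacing (4 s), quantization
cannot move a noiseless vertex to the wrong index. The inclusion threshold
(default 0.2) is strict (`>`); a flag switches to `≥`.

For iso-frequency contours the integer index map is made real-valued by
one pass of geodesic-Gaussian smoothing (FWHM 1 mm) — marching triangles
on a piecewise-constant integer field would yield degenerate output — and
level sets are extracted by linear interpolation on edges, chained into
polylines that are closed or end on the patch boundary.

## GLM

One regressor of interest (18 s ON / 12 s OFF boxcar convolved with the
hemodynamic response), an intercept, an optional linear drift, and
pass-through nuisance columns. Ordinary least squares, t for the contrast
[1, 0, …]; no autocorrelation whitening (the synthetic path uses white
noise, where the null calibration is exact: measured rejection ≈ 0.001 at
p < 0.001 two-sided over 2·10⁴ null vertices). Maps are conventionally
thresholded at two-sided p < 0.001 uncorrected. With percent-signal-change
conditioning, an injected response of amplitude A is recovered with a
small negative bias (≈ A·mean(regressor)/100, ~1% at A = 2%), because the
normalizing mean includes the response itself.

## Geometry

Geodesics are graph geodesics (Dijkstra on triangle-edge lengths; exact
polyhedral geodesics are out of scope). Vertex normals are area-weighted
averages of incident triangle normals; a constructor flag flips them when
the stored winding points toward white matter. Mean curvature is the
cotangent Laplacian of the position function with Meyer's mixed Voronoi
vertex areas, cotangents clamped to ±10⁴, sign from the projection on the
vertex normal (sphere with outward normals: positive, 1/R within 10% on an
icosphere); boundary vertices are set to missing. Geodesic-Gaussian
smoothing uses σ = FWHM/2.3548, truncates support at 3σ (omitted weight
< 1.2%), renormalizes weights per vertex, and excludes missing values from
both sums.

## Flattening

Classical (metric) MDS of the all-pairs graph-geodesic matrix, chosen for
determinism; the top-2 eigenpairs must be positive. A single least-squares
scale factor calibrates the map to geodesic millimetres, and orientation
is made deterministic: axis 1 along increasing posterior→anterior
coordinate, reflection chosen to preserve the majority triangle winding.
On the folded phantom the stress (√(Σ(d_flat−d_geo)²/Σd_geo²), the
d²-weighted RMS relative distance error) is ≈ 1.2%; the median triangle
area ratio sits ≈ 1.15 because short-range graph distances carry the full
metrication stretch that long-range distances average out — a known
property of edge-graph geodesics, documented rather than hidden. Full
all-pairs distances are acceptable at patch scale (≤ ~5000 vertices); no
landmark approximation.

## Myelin index

Depth sampling spans 0–2 mm at 0.25 mm steps (9 samples): 2 mm
approximates macaque cortical thickness and 0.25 mm matches the structural
resampling resolution the pipeline targets. The ±1 SD exclusion is global
across all vertices' samples by default ("of all values"); a per-vertex
variant is available behind a flag. A vertex losing every sample falls
back to its unfiltered mean and is flagged. If the global SD is 0 all
samples are kept. The structural phantom injects ratio 1.5 in a core box
on a 1.0 background with 2% multiplicative noise and ratio-5.0 vessel
spikes at 1% of voxels; the exclusion removes every spike (map maximum
stays below the global m+s band) and the smoothed map recovers the
1.5/1.0 contrast to within the border blur of the 1 mm kernel.

## Problem sizes

Default analysis and acceptance sizes: 40×40-vertex phantom (1600
vertices), 343 volumes/run, up to 4 runs per direction; 40×40×24-voxel
structural phantom at 0.5 mm; 2·10⁴ null vertices for the GLM calibration.
These sizes give stable statistics (binomial error on recovery percentages
< 1 percentage point) while the full test suite and acceptance script run
in seconds.
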