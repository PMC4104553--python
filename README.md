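# tonosurf

Surface-based analysis of phase-encoded tonotopic fMRI for small cortical
patches (monkey auditory cortex scale): best-frequency decoding by
cross-correlation lag, local flattening by multidimensional scaling of
geodesic distances, and a T1w/T2w myelin index sampled across cortical
depth. Because no suitable public dataset accompanies this kind of
acquisition, the package ships a first-class synthetic-data generator that
produces every input with known ground truth, so every stage is testable
end to end.

## The method

**Phase-encoded decoding.** Pure-tone blocks sweep a half-octave series
(500–8000 Hz, 9 tones × 2 s) followed by a 12 s pause; the 30 s cycle
repeats 15 times per run, once low-to-high and once high-to-low
(TR = 1.4 s, 343 volumes/run). A vertex preferring ascending-tone index *k*
responds at onset *k*·2 s in the low-to-high cycle and (8−*k*)·2 s in the
high-to-low cycle, so after per-vertex conditioning (percent signal change,
zero-phase 0.02–0.1 Hz Butterworth band-pass) and run averaging, the lag of
maximum Pearson cross-correlation between the two run types is

δ = (2k − 8) · 2 s,  inverted as  k = round(δ/4 s + 4),

and the hemodynamic delay cancels because it shifts both run types equally.
Vertices are kept where the peak correlation exceeds 0.2 (strict).

**Flattening.** All-pairs graph-geodesic distances along mesh edges
(Dijkstra), then classical MDS: eigendecomposition of −½·J·D∘²·J, top two
axes scaled by √eigenvalue, orientation fixed to the posterior→anterior
axis. Stress √(Σ(d_flat−d_geo)²/Σd_geo²) quantifies residual distortion.

**Myelin index.** The T1w/T2w ratio is sampled every 0.25 mm over 0–2 mm
along each outward vertex normal; samples beyond ±1 SD of *all* sampled
values are excluded (this removes blood-vessel spikes and CSF), the
per-vertex mean of the survivors is smoothed with a geodesic-distance-
weighted Gaussian (FWHM 1 mm).

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
phantom — a developable sheet folded like the circular sulcus, carrying a
high–low–high–low frequency gradient with reversals at y ≈ −10, −3 and
+5 mm and a non-responsive posterior strip:

```sh
python analysis/01_simulate_phantom.py   # writes results/study/ (GIFTI + NIfTI)
python analysis/02_decode_tonotopy.py
python analysis/03_sound_glm.py
python analysis/04_flatten_patch.py
python analysis/05_myelin_index.py
```

`02_decode_tonotopy.py` prints, for the 40×40-vertex phantom:

```
noiseless: median peak r 0.991, exact 100.0%, within +-1 100.0%, non-responsive excluded 100.0%
calibrated_noise: median peak r 0.397, exact 77.3%, within +-1 85.6%, non-responsive excluded 60.9%
```

— with no noise the decoder recovers the ground-truth tone index at every
responsive vertex and the correlation mask removes the whole silent strip;
at the calibrated noise level (median peak correlation ≈ 0.4 across 4
averaged runs per direction, the mask-threshold regime of the method) 86%
of mapped vertices land within half an octave of the truth, while the 0.2
threshold passes ~40% of pure-noise vertices — an inherent property of a
max-over-lags correlation with ~77 effective temporal degrees of freedom
(see `docs/methods.md`). `04_flatten_patch.py` prints

```
flattening: stress 1.16%, retained eigenvalue mass 92.2%, median area ratio 1.146
```

(the fold unrolls almost isometrically), and `05_myelin_index.py`

```
myelin index: core mean 1.499, background mean 1.001 (injected 1.5 vs 1.0, 1% vessel spikes at 5.0)
```

(the ±1 SD exclusion removes every vessel spike: the map maximum stays
below the global mean + SD band).

There is also a CLI over the same stages:

```sh
tonosurf simulate work/ --set n_u=20 --set n_v=20 --seed 3
tonosurf tonotopy work/ --threshold 0.2
tonosurf flatten work/
```

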