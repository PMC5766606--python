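# Methods

This note documents the models, defaults and numerical choices behind
`carpetprf`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Stimulus geometry and aperture construction

The display is a 36.8 × 20.2 cm screen at 1920 × 1080 px viewed from
68 cm. Pixel extents convert to visual angle with the full tangent formula
θ = 2·atan(s / 2d) using the **vertical** pixel pitch (20.2 cm / 1080 px).
This convention reproduces the design's canonical sizes — 428 px → 6.7°
(carpet occluder), 728 px → 11.4° (brick background), 5 px → 0.08°
(fixation dot), 1080 px → 16.9° (vertical screen extent) — and is applied
uniformly; horizontal-pitch conversions differ slightly on a non-square
display and are not used.

A run is 10 s of blank dummy volumes (discarded from analysis, kept in the
convolution timeline) followed by six 30 s trials: bar sweeps Right, Up,
Left, Down with a null trial after the second and fourth sweep. TR is 1 s,
so a run is 190 volumes of which 180 are retained. The bar is 0.9° wide
and 10.9° long (occluder side 6.7° plus 2.1° overlap on each side); within
a sweep its centre advances by 6.7/30° per 1 s step, the centres spanning
the occluder symmetrically (first centre at −3.35° + step/2). The 2 Hz
on/off flicker within each step is ignored at raster level: at TR
resolution the bar is simply "on" for its volume. All three experimental
renderings (illusory contour, occluded bar, low-contrast luminance bar)
share this geometry, so a single binary aperture movie serves every
condition.

The visual-field raster is a ±8.5° square with 0.1° cells, x positive
rightward, y positive upward, origin at fixation. Cells are centre-sampled
(a cell is 1 iff its centre lies inside the bar rectangle). Centre
sampling preserves the bar's area on the raster but can shift its
effective edges by up to half a cell; consequences for oracle comparisons
are discussed under *Numerical choices*.

## Forward model

The pRF is an isotropic 2-D Gaussian with no normalization constant (any
scale is absorbed into the amplitude β). The neural drive per volume is
the sum of the Gaussian over "on" cells times cell area; for a pRF well
inside the grid a full-field frame yields the total mass 2πσ². The HRF is
the canonical double-gamma (peak delay 6 s, undershoot delay 16 s,
dispersions 1 s, peak:undershoot ratio 6, length 32 s), peak-normalized,
sampled at dt = 0.1 s. The drive is upsampled to dt (constant within each
volume), convolved with zero-padded history — physically right for a run
that begins with a blank screen — and sampled at volume onsets. The ±8.5°
grid margin keeps Gaussian truncation below 1% of mass for σ ≤ 2° at
eccentricities ≤ 4°.

Because every aperture frame is a rasterized axis-aligned rectangle, the
frame factorizes into a row mask × column mask, and the drive separates
into two 1-D dot products; because the drive is constant within volumes,
the dt-resolution convolution collapses to a TR-resolution kernel. The
fitter uses this fast path; a unit test pins it to the reference
upsample–convolve–downsample route at < 1e-9.

## Preprocessing and fitting

Per vertex and run: subtract the least-squares line over volumes, z-score
(population sd), then average runs elementwise. "Normalization" is
interpreted as z-scoring; percent signal change is an equivalent
alternative for correlation-based fitting. Zero-variance runs are flagged
and contribute zeros. Null-trial and blank volumes stay in the fit (they
constrain the baseline); only dummy volumes are dropped.

The coarse stage correlates the averaged series against a bank of
unit-amplitude predictions on the grid x₀, y₀ ∈ [−4, 4]° step 0.25°,
σ ∈ {0.2, 0.3, 0.45, 0.67, 1.0, 1.5, 2.25}° (log-spaced); ties break to
the first candidate in (x₀, y₀, σ) order. The fine stage runs Nelder–Mead
on (x₀, y₀, log σ) maximizing R², with β and baseline solved per candidate
by OLS; tolerances 1e-3 on parameters and objective, 400 evaluations per
pass. β is unconstrained in sign.

Two robustness details matter in practice. First, the initial simplex is
explicit (steps 0.25° in x₀/y₀ and 0.2 in log σ, matched to the coarse
grid spacing): scipy's default perturbation is relative to the coordinate
value, which degenerates at the σ = 1 grid point where log σ = 0. Second,
the search restarts once from its converged point with a fresh simplex,
the standard remedy for premature simplex collapse on ridged surfaces.
Together these reduce worst-case noiseless recovery error from ~0.2°
(σ up to 13% off) to < 1e-3° in probe runs. The objective also returns the
worst value outside generous plausibility bounds (centre within the grid,
σ ∈ [0.05°, 10°]), which keeps pure-noise fits off the flat
vanishing-σ/far-field plateaus where β diverges. On simplex failure the
coarse parameters are returned with `converged=False`; a fine stage seeded
at the coarse optimum therefore never reports a lower R² than the coarse
stage.

`PRFMapper` wraps the procedure as a scikit-learn estimator (`fit` on a
(vertex × volume) or (vertex × run × volume) array; per-vertex results in
trailing-underscore attributes and a tidy `results_` table), so it
composes with sklearn tooling; `fit_dataset` maps it over the conditions
of a dataset.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, on
abstract vertices labelled V1/V2/V3:

- **Ground truth**: centres uniform over the carpet square (±3.35°), with
  a configurable fraction (default 0.8) forced inside the 0.75°–3.0°
  analysis band so the ROI filter has work to do; σ uniform in
  [0.4, 0.9]° shifted by +0.2° (V2) and +0.45° (V3), encoding the
  pRF-size increase up the hierarchy.
- **Time series**: the noiseless prediction with β scaled by a condition
  gain × an area gain, plus a linear drift (per-run slope uniform in ±1
  unit) plus stationary AR(1) noise (lag-1 correlation 0.3).
- **Gains**: mapping 1.0, kanizsa 0.25, luminance 0.25, occlusion 0.20;
  areas V1 0.7, V2 1.0, V3 1.3. These are calibration knobs chosen to
  reproduce the ordinal pattern of interest (mapping far above the
  experimental conditions; kanizsa ≈ luminance slightly above occlusion;
  SNR rising V1 < V2 < V3), not measured quantities.
- **Noise level**: white_sd = 5.5 signal units, set by a pilot sweep so
  that the illusion-condition median fitted R² lands near 0.1 (inside the
  0.05–0.15 target window that defines the low-SNR regime of interest);
  the mapping condition then fits at median R² ≈ 0.5.
- **Gaze**: centred Gaussian jitter (default sd 0.3°) at 60 Hz, the
  sampling rate of the eye tracker such experiments use; 225 s per run.

All randomness descends from one root seed through `SeedSequence` spawning
in fixed stream order (truth, runs, gaze), making datasets bit-reproducible.

What the generator does **not** emulate: cortical surface geometry and
vertex adjacency, physiological (cardiac/respiratory) noise spectra,
scanner drifts beyond linear, attention fluctuations, HRF variability
across vertices and subjects, and any systematic pRF-parameter differences
between conditions (the generator shares one ground-truth map across
conditions by construction). Passing tests therefore show the pipeline is
correct and well calibrated under its stated assumptions — not that real
illusory-bar data would yield the same numbers.

## Statistics

- ROI filter: keep vertices with inner ≤ |x₀| ≤ outer on **both** axes
  (bounds inclusive; defaults 0.75°/3.0°), using reference (mapping or
  ground-truth) centres for every condition so the analysed population is
  constant.
- Responsive fraction: strict R² > 0.05. The white-noise Monte-Carlo null
  of the fitted R² at these defaults puts ~87% of pure-noise fits below
  0.05 — the cut has a known ≈13% false-positive rate because R² is
  maximized over a large candidate bank.
- Coherence: per-vertex Pearson r between the observed averaged series and
  the prediction from that vertex's own reference parameters; summarized
  as tanh(mean(atanh r)) with |r| clipped to 1 − 1e-12. The permutation
  test recomputes the summary under uniformly random vertex-to-prediction
  reassignment; one-sided p = (k+1)/(n+1). The implementation forms the
  full vertex × vertex correlation matrix once, so each iteration is a
  gather.
- Parameter consistency: Spearman rank correlation per scalar parameter
  and condition pair; polar angle uses the sin-deviation circular
  correlation about circular means (rotation-invariant, jointly
  negation-invariant). Cells with fewer than 3 complete vertices are NaN.
  An independent implementation (pingouin) cross-checks the circular
  coefficient in the tests.
- Gaze stability: per-axis median absolute deviation, no consistency
  scaling; the compliance bound of interest is 0.5°.

Group-level repeated-measures GLMs are out of scope: the pipeline exports
tidy per-subject tables suitable for any standard statistics package.

## Problem sizes

The test suite and the acceptance script run the study at 300 vertices
(100 per area) × 4 conditions × 4 runs of 180 volumes, a size chosen to
give stable medians and rank orderings on a single CPU in well under a
minute per full fit; the permutation-null calibration uses 200 replicates
of 30 vertices at 500 permutations, and the matched-data test the full
10,000 permutations.

## Known limitations

- At illusion-level SNR (median R² ≈ 0.1) pRF centre estimation is
  information-limited: even an oracle search given the true σ on a dense
  grid shows median centre errors above 0.5° except in the highest-SNR
  area, and the pipeline's median error over all 300 vertices is ≈ 1.1°.
  Low-SNR position estimates should be interpreted at map level (rank
  correlations, coherence tests), not vertex level.
- The raster overlap and the separable closed form agree to ~2% only when
  the closed form is evaluated on the rectangle the raster actually
  encodes; against the nominal rectangle, centre-sampling can shift the
  effective bar edges by up to half a cell, which for σ ≈ 0.3° pRFs
  abutting the bar edge produces relative errors of tens of percent
  (median over random pairs ≈ 1%).
- The fitted σ at low SNR is biased toward the coarse grid's σ values and
  recovered only within ~30% even in favourable areas.
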