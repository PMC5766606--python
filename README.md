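# carpetprf

Population receptive field (pRF) mapping for "carpet" bar-sweep designs, in
which a thin bar traverses a square grey occluder over a textured background
in the four cardinal directions. The scientific question behind such designs
is whether stimuli that carry little or no physical contrast — Kanizsa-style
illusory contours, bars amodally completed behind an occluder, or faint
luminance-defined bars — still drive orderly retinotopic maps in early
visual cortex (V1–V3). Answering it requires exactly the machinery this
package provides: building the binary stimulus aperture from the display
geometry, predicting BOLD time series from a Gaussian pRF model, fitting
those pRFs vertex by vertex at very low signal-to-noise ratios, and testing
whether the resulting maps are *coherent* rather than merely responsive.

The package is aimed at visual-neuroscience researchers who want a tested,
self-contained reference implementation of this analysis, together with a
synthetic fMRI generator with known ground truth, so every stage can be
validated without access to scanner data.

## The model

Each cortical vertex is modelled as a 2-D isotropic Gaussian receptive
field over the visual field,

    g(x, y) = exp( −((x − x₀)² + (y − y₀)²) / (2σ²) ),

with centre (x₀, y₀) and size σ in degrees of visual angle. The neural
drive on volume *t* is the overlap of this profile with the binary stimulus
aperture A_t (1 inside the bar rectangle for that 1 s step, 0 elsewhere):

    d(t) = Σ_cells A_t(x, y) · g(x, y) · Δ²,

and the predicted BOLD signal is the drive convolved with a canonical
double-gamma haemodynamic response function h, sampled at volume onsets:

    ŷ(t) = β · (d ∗ h)(t) + b.

Fitting is coarse-to-fine: a grid search over (x₀, y₀, σ) candidates by
Pearson correlation against a precomputed prediction bank, then a
Nelder–Mead refinement of (x₀, y₀, log σ) maximizing R² (the squared
correlation between prediction and data), with β and b solved by ordinary
least squares. Per vertex the data are linearly detrended, z-scored per run
and averaged across runs. Derived parameters are polar angle
atan2(y₀, x₀) and eccentricity √(x₀² + y₀²).

Map-level statistics follow the standard playbook for this design: analysis
restricted to pRF centres 0.75°–3.0° from either cardinal axis (four
quadrant ROIs inside the carpet), "responsive" defined as R² > 0.05,
map coherence assessed by correlating observed time courses with each
vertex's own reference prediction (summarized by the Fisher-z mean) and by
a permutation test that shuffles the vertex-to-prediction assignment
(10,000 iterations; one-sided p = (k+1)/(n+1)), and between-condition
parameter consistency via Spearman rank correlation — circular correlation
for polar angle. Gaze stability is quantified by the median absolute
deviation of gaze samples per axis.

## Worked example

```python
import numpy as np
from carpetprf import PRFMapper, make_dataset

ds = make_dataset(n_per_area=5, seed=7)            # 15 vertices, 4 conditions
X = ds.series["mapping"].transpose(1, 0, 2)        # vertices x runs x volumes
mapper = PRFMapper().fit(X)
print(mapper.results_.head(5)[["x0", "y0", "sigma", "beta", "r_squared"]].round(3))
print("mean R^2:", round(mapper.score(), 3))
truth = ds.ground_truth
err = np.hypot(mapper.x0_ - truth["x0"], mapper.y0_ - truth["y0"])
print("median centre error (deg):", round(float(np.median(err)), 3))
```

prints

```
      x0     y0  sigma   beta  r_squared
0  2.258 -0.728  0.715  0.187      0.490
1  0.663  2.178  0.796  0.121      0.347
2  1.977 -0.765  0.811  0.093      0.232
3 -3.211  1.538  0.898  0.093      0.244
4 -0.196  3.213  0.621  0.184      0.287
mean R^2: 0.54
median centre error (deg): 0.284
```

Each row is one simulated vertex fitted from its four high-contrast
("mapping") runs: the estimated pRF centre in degrees (x rightward, y
upward from fixation), its size σ, the response amplitude β, and the
goodness of fit. The median distance between fitted and true centres —
0.28°, resolution comparable to the bar step of 0.22° — is the kind of
recovery the high-SNR condition supports; the low-contrast conditions are
far noisier by design.

The same pipeline is scriptable from the shell:

```bash
carpetprf simulate --seed 3 --n-per-area 50 --out data/
carpetprf fit      --data data/ --out fits/fits.csv
carpetprf stats    --data data/ --fits fits/fits.csv --out stats/
```

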