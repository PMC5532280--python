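# vibromap

Multivariate profiling of vibrational microspectroscopy (FT-IR / Raman)
tissue maps.

Hyperspectral vibrational imaging records a full vibrational spectrum per
pixel, turning a tissue section into a label-free chemical map.  Telling
tissue types (or disease states) apart from these maps is hard: the
spectra mix the class-discriminating chemistry with baseline drift,
cosmic-ray spikes, noise, and large within-class variation from biology
and measurement.  `vibromap` implements the supervised chemometric
workflow developed for exactly this setting — profiling pancreatic tissue
(islets of Langerhans vs. exocrine tissue) in models of diabetes — as a
reusable Python library for anyone analysing FT-IR or Raman tissue maps.

## What it does

* **Preprocessing** — cosmic-ray despiking, optional low-rank (PCA) noise
  filtering, trimming to the informative spectral region, asymmetric
  least squares (Whittaker) baseline correction, Savitzky–Golay smoothing
  (1st-order, frame 5) and total-area normalization, with modality presets
  (`ftir`: λ = 5 000, 950–2000 cm⁻¹; `raman-dry`: λ = 10 000,
  630–1890 cm⁻¹; `raman-intact`: λ = 10⁶).
* **OPLS-DA** — orthogonal projections to latent structures discriminant
  analysis.  For C classes the model fits exactly C−1 predictive
  components and at most C orthogonal components on mean-centered data,
  separating between-class from within-class spectral variation.  Every
  pixel of a map is then classified (or assigned NONE when its Hotelling
  T² or distance-to-model exceeds the α = 0.05 critical value), giving a
  false-color class map.  Diagnostics: R²X, R²Y, cross-validated Q²(cum),
  Hotelling T² 95 % confidence ellipses and correlation-scaled loadings
  p(corr) that rank the bands driving the separation.
* **MCR-ALS** — multivariate curve resolution by alternating non-negative
  least squares with SIMPLISMA (pure-pixel) initialization, resolving
  mixture maps into pure spectral profiles and per-pixel concentrations.
* **Synthetic scenes** — a ground-truthed generator of tissue maps
  (analytic Gaussian/Lorentzian bands, lognormal within-class variability,
  smooth baselines, noise, spikes, islet-disc/split/empty layouts) used by
  the test suite and available for method studies.

The model, in the field's notation: with pixel spectra `X` (n × m) and
dummy class responses `Y` (n × C), both centered,

    X = T Pᵀ + Tₒ Pₒᵀ + E ,     Ŷ = T Cᵀ

where `T` are predictive scores (C−1 components, correlated with class),
`Tₒ` orthogonal scores (within-class variation, filtered out before
prediction), and `p(corr)ⱼ = corr(t, xⱼ)` the correlation-scaled loading
of band j.

## Worked example

```python
import numpy as np
from vibromap import OPLSDA, PreprocessConfig, preprocess
from vibromap.simulate import islet_scene, generate, training_mask
from vibromap.mapping import build_training_set, diagnostic_band_report
from vibromap.opls import correlation_scaled_loadings

scene = islet_scene(seed=42, spike_rate=0.02)   # islet disc in exocrine tissue
img, truth = generate(scene)
pre = preprocess(img, PreprocessConfig.preset("raman-dry"))

mask = training_mask(truth, n_per_class=120, erode=2, seed=0)
X, labels, _ = build_training_set(pre, mask)
model = OPLSDA(classes=("islet", "exocrine")).fit(X, labels)

full = model.predict_full(pre.as_matrix())      # classify every pixel
p = correlation_scaled_loadings(model, X)
report = diagnostic_band_report(pre.axis.values, p, threshold=0.5,
                                positive_class="islet", negative_class="exocrine")
```

Output:

```
scene: 40x40 pixels, 631 bands (630-1890 cm-1)
despiked channels: 114
model: 1 predictive + 2 orthogonal components
R2X=0.950  R2Y=0.995  Q2(cum)=0.995
islet Dice vs ground truth: 0.964
empty pixels predicted NONE: 100%
    lo     hi  peak_wavenumber  peak_pcorr                                 label
1668.0 1720.0           1704.0   -0.989313 amide I (protein secondary structure)
1606.0 1662.0           1624.0    0.986706 amide I (protein secondary structure)
 652.0  694.0            666.0    0.980023    -S-S- stretch (insulin-associated)
```

Reading this: the two tissue classes separate on one predictive component
with near-perfect cross-validated predictive ability (Q²(cum) = 0.995);
classifying every pixel reproduces the planted islet region with Dice
0.964 while all empty (no-tissue) pixels are rejected as NONE; and the
band report correctly recovers the planted islet markers — the amide I
envelope difference and the insulin-associated -S-S- band near 673 cm⁻¹.

A CLI mirrors the library: `vibromap simulate | preprocess | fit |
predict | map | mcr | quality | run` (see `vibromap --help`); `vibromap
run --config run.yaml` executes the whole workflow and writes a manifest
with SHA-256 hashes of every artifact.

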