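# Methods

This note documents the models and numerical procedures implemented in
`vibromap`, the assumptions behind them, and the design choices made where
the workflow left a decision open.

## Data model

A map is a grid of spectra on one shared wavenumber axis.  The canonical
axis order is ascending wavenumber; instrument exports in descending
order are flipped at the I/O boundary so every algorithm sees one
convention.  Pixel coordinates are 0-based `(row, col)`, row-major; the
long-format `x` column maps to `col` and `y` to `row`.  Intensities are
held as 64-bit floats regardless of source precision because the baseline
solver involves ill-conditioned penalized systems.  Typical instrument
maps hold 150–4100 spectra; maps beyond 10⁶ pixels trigger a warning.

## Preprocessing chain

Stages run in a fixed order — despike → PCA noise filter → trim → AsLS
baseline → Savitzky–Golay → total-area normalization — and each executed
stage appends a parameter record to the image metadata history, so a run
is reproducible from its manifest.

**Despiking.** Cosmic-ray spikes are one-to-two-channel transients unique
to a pixel.  Channels whose second difference has a modified z-score
(0.6745·|d − median(d)| / MAD) above `despike_z` (default 10) are replaced
by the median of the surrounding window (default 5 channels) excluding
flagged channels; everything else passes through bit-exact.  The second
difference makes the detector insensitive to smooth bands (their
curvature is orders of magnitude below a spike's), and the MAD keeps the
scale estimate robust to the spikes themselves.  When the MAD collapses
(noiseless synthetic spectra) the mean absolute deviation substitutes, so
exactly smooth spectra are never flagged.

**PCA noise filter** (`noise_rank`, off by default): the pixels × bands
matrix is replaced by its best rank-r approximation around the mean
spectrum; `rank="auto"` keeps the components explaining 99 % of variance.
The filter runs per map, not per scan block.

**Trimming** restricts the axis to the informative window inclusively:
950–2000 cm⁻¹ for FT-IR (the fingerprint region), 630–1890 cm⁻¹ for
Raman (removing channels affected by reconstruction artefacts at the
high end).

**AsLS baseline.** The baseline `z` minimizes
`Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with asymmetric weights `wᵢ = p` where
`yᵢ > zᵢ` and `1−p` otherwise, iterated from uniform weights until the
weight vector stops changing (tolerance 1e-6, cap 50 iterations; spectra
hitting the cap are flagged in metadata).  With p = 0.01 the quadratic
penalty forgives points above the baseline, so `z` hugs the lower
envelope and the corrected spectrum keeps the (positive) bands.  Each
inner solve is a pentadiagonal symmetric positive-definite system solved
with a banded Cholesky factorization (`D₂ᵀD₂` has the closed-form band
structure diag [1,5,6,…,6,5,1]).  λ presets per modality: 5 000 (FT-IR),
10 000 (Raman, dry sections), 10⁶ (Raman through intact tissue, where the
background is far stiffer).  The λ=10⁶ preset shares all other defaults.
Baseline recovery error grows as ~(peak width)⁴/λ; for fingerprint bands
(FWHM 20–40 cm⁻¹) the recovered baseline RMSE stays below 1 % of the peak
amplitude at these presets.

**Savitzky–Golay** (frame 5, order 1): each point is replaced by the
value at the window center of the least-squares polynomial over the
frame.  For order ≤ 1 and a full window this equals the moving average.
Edges use truncated windows with the polynomial refit (no reflection
padding — nothing is fabricated beyond the spectrum ends, and the
contract is exactly checkable against a brute-force windowed fit).  The
whole operator is precomputed as an n × n banded matrix, so smoothing a
map is one matrix product.

**Total-area normalization** rescales each spectrum to unit intensity
sum.  "Area" is the plain channel sum (axis spacing is uniform after
trimming), which makes the unit-sum invariant exact and the operation
idempotent.  Spectra with non-positive total (empty-region pixels after
baseline subtraction) are flagged `unnormalizable`, returned unchanged,
and excluded from model fitting downstream.

## OPLS-DA

With centered spectra `X` (n × m) and centered one-hot class responses
`Y` (n × C):

1. The predictive weight span `W_y` is the orthonormal basis of the
   columns of `XᵀY`.  Orthogonal deflation leaves `XᵀY` invariant
   (orthogonal scores are exactly uncorrelated with every `Y` column), so
   the basis is computed once.
2. Per orthogonal component: take the X-loading `p` of one NIPALS PLS
   component of the current `X` against `Y`; the orthogonal weight is
   `w_o = p − W_y(W_yᵀp)`, normalized; scores `t_o = X w_o`, loadings
   `p_o = Xᵀt_o/(t_oᵀt_o)`; deflate `X ← X − t_o p_oᵀ`.
3. An ordinary NIPALS PLS2 model with exactly C−1 components is fit on
   the filtered `X`; predictions use `W* = W(PᵀW)⁻¹`, class assignment is
   the argmax of the predicted dummy responses (ties deterministically to
   the lower class index, with a warning).

For two classes this construction is prediction-equivalent to a plain
PLS regression with (1 + n_ortho) components — the strongest single
correctness check in the test suite, verified against scikit-learn's
PLSRegression to 1e-8.

**Orthogonal component count.**  The cap is C (the class count).  With
`n_ortho="auto"` extraction stops early when a component explains < 1 %
of the X variance (`ortho_var_min`) or when the cross-validated Q²
decreases; the retained count is exposed as `n_ortho_` and logged per
run rather than guessed.

**Cross-validation.**  Q²(cum) = 1 − PRESS/SS_Y over 7 deterministic
interleaved folds (`row index mod folds`); each fold's model is refit
with the parent's retained orthogonal count.  A fold that would strip a
class from the training split raises an error naming the fold.  Model
quality (R²X, R²Y, Q²(cum), folds) is computed at fit time whenever
n ≥ folds.

**Hotelling T² ellipse.**  For a 2-D scores plot the 95 % boundary is at
`T²crit = 2(n−1)/(n−2)·F₀.₀₅(2, n−2)`, axes along the score-covariance
eigenvectors with semi-axes `sqrt(T²crit·eigenvalue)`.  Note this is the
classical in-sample form: for points that themselves estimated the
covariance the exact in-sample coverage at n = 100 is ≈ 0.959 (the
in-sample T² is Beta-distributed), which is what the coverage simulation
measures.

**Outlier ("NONE") rule.**  A predicted spectrum is assigned NONE —
i.e. not described by the model, such as empty-region pixels — when its
Hotelling T² over all model components *or* its DModX exceeds the
critical value.  The two component tests are Bonferroni-split at α/2 so
the union test has overall size α (default 0.05): a plain union of two
5 % tests would reject ~10 % of perfectly ordinary tissue.  DModX is the
per-spectrum residual standard deviation after removing the model
structure, normalized by the pooled training residual.  Its critical
value is the larger of the F-based variance-ratio bound and the
empirical (1−α) quantile of the training DModX distribution: tissue
spectra have genuinely heavy-tailed residuals (within-class band
amplitude variation the C-capped component set cannot absorb), and the
F bound alone, derived under iid Gaussian residuals, would flag a large
fraction of unremarkable pixels.  The calibrated cut-off keeps the
training flag rate at ≈ α while leaving empty-region pixels an order of
magnitude beyond it.

**Correlation-scaled loadings.**  `p(corr)ⱼ` is the Pearson correlation
between a predictive score and centered band j over the training set,
bounded in [−1, 1]; positive values mark bands more intensive in classes
scoring positive on that component.  Zero-variance bands get 0 with a
warning.  Note 0.2 is a *per-band* 95 % null bound at n = 200; the
maximum over hundreds of null bands is naturally larger.

## MCR-ALS

The mixture model is `D ≈ C S` with non-negative concentrations `C`
(n_pixels × k) and profiles `S` (k × n_bands) — the only constraints
used.  Initial profiles come from pure-pixel SIMPLISMA: the purity of
row i is `sᵢ/(mᵢ + α·max(m))` (row std over offset mean, α = 0.05 noise
correction), re-weighted after each pick by the Gram determinant of the
length-normalized selected rows, which deflates candidates collinear
with earlier picks; a vanishing determinant (no further pure direction)
raises an error.  SIMPLISMA runs on raw rows, not derivatives.

Each half-update solves its constrained least-squares subproblem exactly
(active-set NNLS per column), which guarantees the reconstruction error
— tracked as LOF % = 100·√(Σ(D−CS)²/ΣD²) — never increases.  Iteration
stops when the relative change in LOF drops below `conv_limit` percent
(default 0.1, the convention of the canonical MCR-ALS implementations),
when the fit is numerically exact (LOF < 1e-9), or at `max_iter` = 50.
The scale ambiguity is fixed by unit-sum profiles with compensated
concentrations; the permutation ambiguity is left to the caller (tests
align by best-permutation cosine).

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes,
not the physics of any instrument:

* per-class spectra as sums of analytic Gaussian/Lorentzian bands on an
  FT-IR (950–2000 cm⁻¹, 4 cm⁻¹ spacing) or Raman (630–1890 cm⁻¹, 2 cm⁻¹
  spacing) axis;
* within-class variability as per-pixel, per-band lognormal amplitude
  scaling (σ = 0.15 default) — a multiplicative "biodiversity" model that
  gives OPLS-DA genuine orthogonal structure to filter;
* smooth polynomial baselines with lognormal per-pixel scale, iid
  Gaussian noise (σ = 0.01 against band amplitudes of order 1 — chosen
  once as a realistic mid-range SNR and exposed in the scene config),
  and Bernoulli cosmic-ray spikes;
* spatial layouts: islet disc inside an exocrine background with an
  empty margin, a two-region split, or a single region with empty
  margin.  EMPTY pixels carry baseline + noise only and are included by
  default so the NONE pathway is always exercised.

Band anchors: the islet profile carries the insulin-associated -S-S-
band at 673 cm⁻¹ and an α-helix-side amide I band; the amide I sub-band
centers used for planting secondary-structure effects (1654 α-helix,
1625 β-sheet) are generator conventions.  `disease_effect` derives new
scenes by shifting a band center (area-conserving), scaling a band, or
adding one — emulating reported disease signatures such as a β-sheet
shift or added collagen intensity.  `training_mask` emulates expert
labeling of unambiguous pixels: class regions eroded away from
boundaries, then subsampled.

Draws use NumPy's seeded PCG64 generator, so scenes are bit-reproducible
across platforms.

What passing tests on these scenes does *not* show: robustness to Mie
scattering and resonance distortions, instrument line-shape effects,
spatially correlated noise, label errors, or co-registration issues —
none of which the generator models.

## Sizes, tolerances and degenerate inputs

The test and acceptance workloads use 40×40-pixel maps (631 Raman
bands), 100–200 training spectra, 10⁴ replicates for ellipse coverage —
sizes chosen so recovery statistics are stable while the whole suite
runs in seconds to minutes on one CPU.  Determinism is exact: no stage
has internal randomness, so identical inputs give bit-identical outputs
and identical artifact hashes.  Degenerate inputs fail loudly with typed
errors: zero-variance X, all-zero mixture matrices, rank-deficient
SIMPLISMA targets, singular score covariances, axis/band mismatches,
masks with too few labeled pixels per class (minimum max(3, n_pred+2)).

## Known limitations

* No atmospheric/scatter corrections (CO₂, water vapour, EMSC/SNV) and
  no readers for proprietary binary instrument formats — export to text
  first.
* Class assignment is uncalibrated argmax; no probabilistic membership.
* MCR-ALS supports non-negativity only (no closure/unimodality).
* FT-IR and Raman maps of the same section are not co-registered.
* False-color maps use flat class colors; score magnitudes are available
  in the TSV export rather than blended into the rendering.
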