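# Methods

This note records the models, conventions and numerical choices behind
`grainspec`, and what the synthetic-data experiments do and do not
demonstrate.

## The measurement model

A push-broom NIR imaging spectrograph samples 254 bands over roughly
866–1701 nm. The band axis is modeled as linear over the 220-band analysis
window 931.8–1653.8 nm (bands 20–239), with the same spacing
(1653.8 − 931.8)/219 ≈ 3.297 nm extrapolated to the 20 leading and 14
trailing edge bands. Anchoring the analysis window (rather than the sensor
extremes) makes the standard 254 → 220 band trim exact; the implied sensor
range, 865.9–1700.0 nm, matches the nominal one to within a band.

Raw digital numbers are converted to relative reflectance by black/white
correction, `R = (I − B) / (W − B)`. Reference frames may be full-size or a
single line broadcast along the scan axis (push-broom practice). Entries
with `W − B ≤ 1e−9` DN are masked to zero and counted. Negative reflectance
(noise pushing `I` below `B`) is **kept** by default — clipping would break
the linearity that multiplicative scatter correction relies on — with an
explicit `clip_negative` option and a logged count.

## Synthetic study conditions

The generator stands in for the undeposited camera data and defines the
conditions every test and the acceptance script run under:

* **Classes.** Four classes share one deterministic baseline (a fixed sum of
  three broad Gaussian humps over the grid, values ≈ 0.3–0.65) and differ
  only by a Gaussian absorption dip at 1520 nm (σ = 60 nm) of depth 0,
  0.04, 0.08, 0.12 reflectance units for classes 1–4. The dip sits inside
  1400–1650 nm, the window where C–H/N–H overtone absorption makes residue
  classes separate in practice, and its monotone depth reproduces the
  untreated > 1:1000 > 1:500 > 1:100 ordering of window-mean reflectance.
  Depths are design choices, not measured values: they are set so that the
  class-mean ordering is stable at 25 kernels/class (≈3σ between adjacent
  class means under the default scatter) while leaving raw-spectrum
  classification visibly harder than scatter-corrected classification.
* **Scatter.** Each kernel (table row or scene grain) gets one affine
  distortion `x ↦ (1+s)·x + o`, `s ~ N(0, 0.03²)`, `o ~ N(0, 0.01²)` —
  exactly the nuisance MSC inverts. Additive white Gaussian noise
  (σ = 0.004 reflectance) acts per band and pixel.
* **Geometry.** Kernels are rotated ellipses (semi-axes 9–12 × 6–8 px),
  placed by rejection sampling with disjoint bounding circles and a 6 px
  margin on a 400 × 400 px image; the default scene holds 4 × 25 = 100
  kernels, a desk-scale analogue of the 4 × 100-kernel experiment (the
  spectra-table path uses 4 × 100 directly). The margin guarantees that the
  radius-2 morphological closing cannot bridge neighbouring kernels.
  Background reflectance is 0.02 — dark but nonzero, so segmentation is
  nontrivial.
* **DN synthesis.** True reflectance is converted to raw DN by inverting the
  correction (`I = R(W−B) + B`, dark 100 DN, white 3500 DN, frame noise
  σ = 0.5 DN). With frame noise disabled and `float64` frames the
  correction recovers the true reflectance exactly (machine precision);
  the default cube dtype is `float32` for memory, as real ENVI exports are.

What passing tests show: the chain is algebraically correct, leakage-free,
and recovers planted structure (dip bands, class labels, kernel geometry)
under realistic scatter and noise. What they do not show: performance on
real kernels, where class differences are subtler, scatter is not exactly
affine, kernels touch, and the informative bands are not known a priori.
Accuracies on the synthetic scenes (often 100%) are analogues of the
qualitative findings — MSC best among pretreatments, SVM best among
classifiers, object-wise mapping reliable — not predictions of real-data
accuracy.

## Segmentation

The mask chain is Sobel gradient magnitude of a band-averaged scalar image →
Otsu threshold → morphological closing (disk radius 2) → hole filling → a
final erosion (disk radius 1). The closing radius, threshold method,
8-connectivity and 50 px minimum area are configurable defaults. The final
erosion is a deliberate addition: an edge-threshold mask keeps a ~1 px halo
outside the true boundary after hole filling, and re-centering the contour
is what lets the default scene be recovered at ≥ 0.95 mean per-kernel IoU.
Watershed splitting of touching kernels is deliberately omitted — scenes
are generated non-overlapping, as the physical experiment arranged separated
kernels. Object spectra are plain arithmetic means over region pixels.

## Pretreatments

* SNV uses the n−1 standard deviation, so `[1,2,3] → [−1,0,1]` exactly;
  constant rows are an error naming the row.
* The MSC reference is the column mean of the **calibration** rows and is
  frozen into the pipeline state; prediction rows and scene kernels are
  corrected against it without refitting (no leakage). Rows with fitted
  slope |b| < 1e−12 are rejected.
* SG1 differentiates per band index (the analysis grid is uniform in nm, so
  the nm-derivative is proportional); window 11 / order 2 defaults, boundary
  values from one-sided polynomial fits. Trimming precedes differentiation
  in the pipeline.

## Wavelength selectors

* **SPA.** Columns are mean-centered (calibration statistics); chains grow
  by maximal residual norm after projecting out the selected columns, ties
  to the lowest band index. Every (start band, prefix size m ∈ [1, 20])
  subset is scored by MLR RMSEV on an internal seeded 75/25 split of the
  calibration rows (the paper-style "validation set" being otherwise
  unspecified); the global minimum wins, ties to smaller m then lower
  start. `m_max` must respect the OLS rank budget.
* **Random frog.** Subset size proposals `Q* = max(1, round(|N(q, θq)|))`
  with θ = 0.3 around the current size q; growth draws a random candidate
  pool of 3 × (Q*−q) outside bands and keeps the best by inner-model
  coefficient magnitude, shrinkage keeps the Q* most important members.
  The inner model is PLS regression on the numeric labels with components
  ≤ min(A = 10, |V|, rank), scored by 5-fold RMSECV on folds fixed for the
  whole walk; worse proposals are accepted with probability
  η · RMSECV/RMSECV*, η = 0.1. Selection probabilities are the fraction of
  the N = 1000 iterations containing each band (the per-iteration subset
  sizes are stored so the counting identity Σpⱼ = mean |V| is
  re-derivable); the default threshold is 0.7. Class labels are treated as
  numeric 1–4 in the SPA/frog inner models — the usual chemometrics
  convention when a regression selector feeds a classifier.
* **NCA.** Features standardized internally; stochastic-1-NN reference
  probabilities `p_ij ∝ exp(−d_w(xᵢ,xⱼ)/σ)` with the weighted Manhattan
  distance `d_w = Σ_r w_r² |x_ir − x_jr|`, σ = 1; objective
  `F(w) = meanᵢ pᵢ − λ Σ w_r²`, λ = 1/n by default. F is climbed with
  L-BFGS on the analytic gradient (a quasi-Newton gradient method; at a
  stationary point the ridge term forces uninformative-band weights to
  exactly zero, which a fixed-rate ascent reaches only asymptotically).
  `w = 0` is always a stationary point of F, and with few samples the
  ridge term at the all-ones start can drag the search into it — so the
  optimizer runs from two deterministic starts (all-ones and all-1/√p) and
  keeps the better objective. Bands with `w² ≥ 0.05 · max w²` are selected
  (relative rule; an absolute rule is available).

Empty selections are returned as warning results; the pipeline and grid
treat them as cell failures rather than silently falling back.

## Classifiers and evaluation

One shared, seeded, **non-stratified** 3:1 random split (400 → exactly
300/100; realized per-class counts are logged, mirroring how such studies
report them). Tuning is k-fold CV accuracy (k = 5) over fixed grids —
minleaf ∈ {1,2,…,64}, k ∈ {1,3,…,15}, (c, g) ∈ 2^{−5..15} × 2^{−15..3} —
with ties to the simplest model (largest minleaf | smallest k | smallest c,
then largest g). Folds are plain k-fold; a fold whose training part misses a
class triggers a reseeded redraw (bounded). Features are standardized with
calibration statistics before KNN/SVM (distance-based models need scale
control; trees do not); SVM is RBF with one-vs-one multiclass voting. Band
selection depends only on (pretreatment, selector), so the benchmark grid
computes each such pair once and shares it across the three classifier
families — an exact reuse, since all cells share one split.

## Problem sizes

The test suite and acceptance script run the spectra-table analyses at the
study scale (400 kernels × 220 bands; the full benchmark grid in the test
suite uses 100 kernels) and the image chain on the default 400 × 400 px,
100-kernel scene; exactness checks use small float64 scenes. These sizes
were chosen as the smallest that exercise every code path at the study's
statistical structure.

## Known limitations

* The generator's radiometry is schematic: no spectral smile/keystone,
  detector response curves, stray light, or actual residue absorption
  chemistry; dip depths are tuning choices, not measured values.
* SPA's validation split and the frog candidate-pool mechanics follow the
  cited algorithms' common conventions where the source descriptions are
  silent; both are exposed as parameters.
* `A = 10` is interpreted as the inner latent-variable cap of the frog
  model (the alternative reading — candidate-pool size — is a separate,
  exposed knob).
* Pixel-wise mapping is intentionally not implemented; the object-wise mean
  is the supported mode.
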