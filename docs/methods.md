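# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `leafspec`.

## Problem setting

A line-scan hyperspectral camera images detached leaves during storage;
each sample yields one mean reflectance spectrum over the segmented leaf
area, and a wet-lab reference measurement yields the four pigment contents
(Chla, Chlb, Chlt = Chla + Chlb, Car, in mg per g fresh weight). The
regression task maps the spectrum to the four contents, either with one
model per pigment (single-task) or one model for all four (multi-task).
Two camera ranges are emulated: VNIR 400–1000 nm, where the chlorophyll
and carotenoid absorption bands live, and NIR 900–1700 nm, dominated by
leaf-water features.

## Synthetic study generator

The generator replaces an instrument and a greenhouse; every constant is
config-pinned.

**Design.** Unpackaged: 4 storage periods (0/3/6/9 h) × 15 leaves × 2
acquisition days = 120 samples per camera. Packaged (cling film): 5
periods (0/3/6/9/24 h) × 30 leaves = 150 samples. These counts are the
study conditions every downstream stage is tested under.

**Pigment decline.** Mean content at hour *t* is `c₀·exp(−k·t)` per
pigment, with `k(unpackaged) ≥ k(packaged)`; individual leaves multiply
the mean by `exp(σ·Z)`, `Z ~ N(0,1)`, σ = 0.12. Defaults (fresh spinach
scale): c₀ = 1.82 / 0.72 / 0.38 mg/g for Chla / Chlb / Car; decay rates
0.045 / 0.040 / 0.030 h⁻¹ unpackaged and 0.012 / 0.010 / 0.008 h⁻¹
packaged. A moisture level `exp(−k_w·t)` (k_w = 0.030 vs 0.005 h⁻¹)
drives the NIR water bands. Chlt is always recomputed as Chla + Chlb.

**Forward optics.** Reflectance is a smooth leaf-like baseline (logistic
red edge at 715 nm rising from 0.32 to 0.80 for VNIR; a gently declining
plateau for NIR) minus Gaussian absorption bands whose depth is *linear*
in the driving quantity: Chla at 675 and 430 nm, Chlb at 650 nm, Car at
490 nm, water at 1200 and 1450 nm. Band depths are sized so that the
default study stays inside the [0.01, 0.99] clipping range — within it the
spectrum is an exactly linear function of the pigment panel, which is what
makes the parameter-recovery tests sharp. Bands whose center falls outside
the camera grid are skipped with a warning.

**Scene rendering.** A leaf ellipse on a dark background (reflectance
0.008), constant dark offset (100 counts) and white level (4000 counts),
additive Gaussian count noise. Counts are
`B + (W − B)·R + ε`, so black-white correction inverts the render exactly
when ε = 0; this round trip (≤ 1e-9 per pixel, ≤ 1e-6 after segmentation
and averaging) is the oracle for the whole extraction pipeline.

**What the generator does not emulate:** radiative-transfer leaf optics,
specular highlights, scanner motion blur, multi-leaf scenes, wavelength-
dependent lamp spectra, pigment–pigment interactions. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and that
the models can recover a known linear spectra→pigment map at study scale —
not that any given field dataset will reach the same accuracy.

## Extraction pipeline

`I = (S − B)/(W − B)` elementwise, with an explicit error naming the first
pixel/band where W ≤ B. Segmentation binarizes a single bright-leaf band
(nearest 800 nm for VNIR, 1100 nm for NIR) with Otsu's threshold followed
by one intermeans refinement — recentring the threshold to the midpoint of
the two class means. The refinement exists because on synthetic scenes the
background histogram collapses into one or two bins and the tie-broken
Otsu threshold can park at the cluster edge; for ordinary images the
refinement is a no-op within a bin width. Components smaller than 50 px
are removed; a fixed threshold can override Otsu. The mean spectrum over
the mask represents the sample. Trimming keeps exactly the bands inside
the closed intervals [475, 980] nm (VNIR) or [970, 1670] nm (NIR), by
wavelength comparison rather than band index; no smoothing, SNV or MSC is
applied anywhere.

## Reference chemistry

Concentrations (µg/mL) from the absorbance triple at 665/649/470 nm in
95% ethanol: `Ca = 13.95·A665 − 6.88·A649`,
`Cb = 24.96·A649 − 7.32·A665`,
`Car = (1000·A470 − 2.05·Ca − 114.8·Cb)/245`; contents are
`C·V/(1000·m)` mg/g for volume V (mL) and mass m (g). The coefficient set
is pinned in `PigmentCoefficients` so another solvent calibration can be
swapped in. Computed concentrations below zero (possible for noisy
triples) are floored at zero with a warning.

## Outlier screen and split

One PLS1 model per pigment is fitted to *all* samples (centering only);
absolute residuals above a per-pigment threshold flag the sample, and the
union rule removes a flagged sample from all four tasks so that every
model family trains on identical data. Thresholds default to
mean + 3·SD of each pigment's residuals — a reproducible stand-in for a
manual choice — and are overridable per pigment. The screen's component
count defaults to the minimizer of an unshuffled 5-fold CV RMSE (capped at
15); training-set residuals alone would always prefer the cap. The
retained samples are split 3:1:1 by a seeded permutation with
nearest-integer rounding for the train and validation blocks (100 →
60/20/20, 101 → 61/20/20); the same assignment serves single- and
multi-task models.

## Models

**PLS.** `sklearn` PLS with `scale=False` (centering only). Single-task =
PLS1 per pigment; multi-task = PLS2 on the 4-column block. The latent
count is chosen by grid search on validation RMSE (multi-task: mean over
tasks), ties to the smaller count; the chosen count is verified in tests
against an exhaustive brute-force re-fit.

**Task weighting.** `wᵢ = 0.25/Var(yᵢ)` on the training targets (sample
variance), so `wᵢ·Var(yᵢ) = 0.25` holds per task. The multi-task loss is
the mean of the four weighted task MSEs, `L = ¼ Σ wᵢ·MSEᵢ`. Note the
identity: weighting by 0.25/var is exactly ¼ × the MSE of the
per-task-standardized target, which is why the weighting also acts as the
target normalization for multi-task nets.

**Networks.** A small numpy engine provides Conv1d ('same' padding,
stride 1), BatchNorm1d, ReLU, MaxPool1d (size 2), Flatten, Dense, and
Adam; forward/backward passes are explicit and checked against finite
differences in the test suite, and gradients with respect to intermediate
activations are first-class (needed for Grad-CAM++). BPNN: one hidden
ReLU layer (default width 32). CNN variants: `vnir` = two conv blocks
with a second conv layer in block two (3 conv layers total); `nir` = two
blocks, one conv layer each; `nir_small` = one block (used where a
shallower net generalizes better, e.g. the packaged-Car NIR task). Each
block is conv → batch-norm → ReLU → max-pool; the head is two dense
layers. Defaults: kernels 7 then 5, channels 16 then 32, head width 64,
Adam 1e-3, batch 16, ≤ 800 epochs with patience-100 early stopping on
validation loss (BPNN: ≤ 2000/patience 200 — its epochs are cheap and the
small net converges slowly on low-variance targets); the parameters of
the best-validation epoch are returned. Training is bit-reproducible for
a fixed seed.

**Input/target scaling.** Net inputs are centered per band and scaled by
one *pooled* SD. Per-band autoscaling was evaluated and rejected: flat
plateau bands carry almost pure sensor noise, and inflating them to unit
variance both degraded generalization (test r dropped from ≈ 0.99 to
≈ 0.5 under realistic noise) and smeared saliency over uninformative
bands. Targets are centered per task; single-task targets are also scaled
to unit SD (for multi-task the variance weighting already provides the
scale, see the identity above). The output layer is zero-initialized so
training starts exactly at the training-set mean — this also makes the
degenerate constant-target case exact from the first step. PLS sees raw
(centered-only) spectra; the stored spectra tables themselves are never
transformed.

## Grad-CAM++ in 1-D

For a CNN and one task, the scalar score is that task's output. With
activations A of the last convolutional layer and gradients g = ∂score/∂A
(computed by the engine's backward pass in inference mode), the channel
weights use the standard first-order form of the Grad-CAM++ formula,

    α = g² / (2·g² + Σ_l A·g³),    w_c = Σ_l α·relu(g),

which is the closed form of the second-order weights under the usual
exponential-score assumption. The map is `relu(Σ_c w_c·A_c)`, averaged
over the batch (default: the test set), interpolated from conv positions
to band centers (each position covers `stride` bands; its weight is
placed at the window center), and max-normalized to [0, 1]. A constant
output yields an all-zero map with a warning flag. Peaks and valleys are
strict local extrema within a ±5-band neighborhood (configurable), with
the global extremum flagged.

**Resolution caveat.** Every pooling stage halves the map's wavelength
resolution: with two pools the deeper variants localize a 12 nm-wide
generating band to only ±15 nm in roughly 6 of 10 training seeds, while
the single-block variant manages 9 of 10. Saliency analyses in this
package therefore default to the shallowest architecture that fits the
task, and the localization check in the acceptance suite trains the
single-block variant.

## Numerical choices and degenerate inputs

* Calibration refuses any pixel/band with W ≤ B, naming the position.
* Segmentation raises on zero-contrast images and on empty masks after
  cleanup; `min_area` defaults to 50 px.
* PLS grid ties break to the smaller component count (absolute tolerance
  1e-15 on validation RMSE).
* Trainer aborts with a diagnostic when the loss exceeds 1e6 or becomes
  non-finite; a zero-epoch budget returns the initialization.
* `r` is undefined (error) for constant references or fewer than two
  points; RMSE is reported in mg/g throughout.
* Variance weights reject non-positive target variances.
* Standardization floors: pooled SD ≥ 1e-8; single-task target SD ≥ 1e-12.

## Problem sizes

The test suite and the acceptance script run the study at its designed
scale (120/150 samples, 224-band grids trimmed to 188 retained VNIR
bands) for the generator, pipeline, PLS and outlier stages. Network fits
use the designed 150-sample set with early stopping; the saliency
localization check trains ten single-block CNNs at 300 epochs each. These
sizes keep a full run in the low minutes on one CPU while exercising
every stage at study scale.

## Known limitations

* The synthetic forward model is linear-in-pigments by construction;
  near-perfect PLS recovery on it says nothing about nonlinear matrix
  effects in real leaves.
* The decay/optics constants are plausible for spinach but are not fitted
  to any measured dataset; per-period pigment distributions of a real
  study cannot be reproduced, only emulated in shape.
* Grad-CAM++ localization degrades with pooling depth (see above) and
  inherits the usual caveats of activation-based saliency.
* The outlier thresholds of a manual screen cannot be recovered; the
  mean + 3·SD default is a convention, and removed counts will differ
  from any specific manual analysis.
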