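# Methods

## Overview

`tilscore` quantifies tumor-infiltrating lymphocytes (TILs) on H&E slide
images at the patch level. A slide raster is cut into non-overlapping
150×150 px tiles (assumed ×20 magnification, ≈0.5 µm/px), blank tiles
are discarded, tissue tiles are Macenko color-normalized, each tile is
assigned one of three classes — TIL-positive (0), TIL-negative (1),
other/necrotic (2) — and the class counts are pooled into a TIL score
per slide and per patient. A seeded synthetic H&E generator with exact
ground truth makes every stage testable without any real slide.

## Patch labeling rule

A patch is TIL-positive when it contains at least 3 detected lymphocytes
*and* at least 1 detected tumor cell; TIL-negative when it contains at
least 1 tumor cell and fewer than 3 lymphocytes; other/necrotic when it
contains no tumor cell, regardless of lymphocyte count. The rule is a
total partition of count space (`rule_label`), and stromal vs
intratumoral lymphocytes are deliberately not distinguished.

## Blank filter

With per-pixel gray g = (R+G+B)/3, a tile is blank iff mean(g) > 230 and
population sd(g) < 15, both inequalities strict. The statistic is
computed on per-pixel gray by default; a pooled per-channel variant is
available (`BlankFilterParams.per_channel`) since either reading of
"average values of RGB" is defensible.

## Beer–Lambert rendering and optical density

Synthetic patches are rendered as `I = Io · exp(−S c)` per pixel, with
`Io = 240`, `S` the 3×2 unit-column stain matrix (hematoxylin, eosin)
and `c` the per-pixel concentration pair; Gaussian intensity noise of
standard deviation `noise_sd` (0–255 scale) is added before 8-bit
quantization. The inverse transform is `OD = −ln((I+1)/Io)` clipped
below at 0; the +1 makes intensity Io−1 map to OD exactly 0 and the
round trip exact for I ∈ [0, 239]. Concentrations are recovered by
least squares with negatives clipped (exact NNLS behind
`MacenkoParams.use_nnls`); recovery error from quantization scales as
1/I per pixel.

The default stain matrix and concentration scales are the widely used
reference values (H = [0.5626, 0.7201, 0.4062], E = [0.2159, 0.8012,
0.5581], 99th-percentile concentrations [1.9705, 1.0308]); the same
profile is the default normalization target.

## Synthetic morphology

* Lymphocytes: disks of radius 5–7 px with hematoxylin concentration
  U[0.8, 1.2] — small, round, darkly stained.
* Tumor nuclei: radially perturbed ellipses (semi-axes 12–20 px, radial
  jitter up to ±25 %, low-order angular frequency) with hematoxylin
  U[0.4, 0.8] and an eosin cytoplasm halo U[0.1, 0.3] — enlarged,
  irregular, paler.
* Stroma background: a smooth eosin gradient field spanning
  U-range [1.2, 2.2] with gentle sinusoidal fiber texture. Two
  considerations set this range high: pure-eosin pixels only clear the
  Macenko OD floor (β = 0.15 on every channel, eosin red component
  0.216) at concentrations above ≈0.7, and the spatial spread of the
  field is what anchors the eosin axis of the OD covariance eigenplane.
* Non-tissue background renders at Io (near-white) and passes the blank
  filter by construction.

Nuclei are placed by rejection sampling with non-overlapping envelopes
and a 5 px minimum gap (so the reference detector never needs to split
touching nuclei); infeasible requests raise `CapacityError` after
bounded attempts and a few whole-layout restarts. Halos may overlap
anything; nuclei are painted last and exclude eosin. Per-patch seeds in
slides and datasets are counter-based
(`SeedSequence((master_seed, row, col))`), so any patch can be
re-rendered in isolation and generation is bit-reproducible.

Class mixes default to 1 : 1.5 : 1.5 (positive : negative : other), the
composition used for classifier training sets; per-class count ranges
(positive: 3–8 lymphocytes, 1–3 tumors; negative: 0–2, 1–3; other: 0–5
lymphocytes, no tumor) respect the labeling rule by construction.
Dataset class counts follow largest-remainder apportionment, ties to
the lowest class code.

What the generator does **not** emulate: touching/overlapping nuclei,
mitoses, necrosis texture, tissue folds, pen marks, scanner bokeh and
compression artifacts, and cells straddling patch borders. Passing
tests therefore demonstrate the correctness of the pipeline's logic and
numerics, not detector performance on real histology.

## Macenko normalization

Implementation follows the standard procedure: OD pixels with every
channel above β = 0.15 are eigen-decomposed; pixels are projected onto
the top-2 eigenplane; the α = 1 and 99th angle percentiles give the two
stain directions (sign-fixed non-negative, unit-norm; hematoxylin is the
vector with the larger red OD component); concentrations come from
least-squares unmixing, and the 99th percentile per stain defines the
profile's concentration scale. Normalization rescales concentrations by
`target.max_concentration / source 99th percentile` and re-renders with
the target matrix and Io. Defaults io = 240, α = 1, β = 0.15 are the
standard hyperparameters of this algorithm.

Degenerate inputs — fewer than 100 tissue pixels, or recovered stain
directions closer than 10° (effectively single-stain) — raise
`DegenerateStainError` in estimation and pass through unchanged (with a
flag) in normalization.

Two conditioning facts shaped the surrounding design, established by
noise-propagation analysis and numerical experiment during development:

1. **Estimation needs a filled stain cone.** On images whose OD pixels
   form two tight clusters (pure nuclei, pure stroma), the in-plane
   variance orthogonal to the dominant stain direction is suppressed by
   sin²(22°) ≈ 0.14 — the angular separation of the H and E vectors —
   and at pixel noise sd ≈ 8 the anisotropic average noise covariance
   overwhelms it, tilting the eigenplane by tens of degrees no matter
   how many pixels are available. Stain-estimation accuracy is
   therefore verified on calibration phantoms
   (`generate_stain_phantom`): synthetic targets whose per-pixel
   concentrations independently and uniformly span the cone, as the OD
   cloud of richly mixed real tissue does. On phantoms the estimator
   recovers the stain vectors to well under 1° noiselessly and ≈2.5–3°
   at noise sd 8; on noiseless tissue patches, under 1°.
2. **Normalization must not do harm it cannot detect.** Because
   per-patch estimation is unreliable above a measurable noise level
   (error ≤ 2° at noise sd ≤ 2, ≥ 12° at sd ≥ 4 on sparse tissue
   patches), `normalize_patch` estimates the image noise (wavelet
   estimator) and passes the patch through, flagged, when it exceeds
   `MacenkoParams.max_noise_sd = 2.5` — the knee of that error curve.
   This keeps the end-to-end pipeline well-behaved on noisy input at
   the cost of leaving such patches in their original colors.

## Reference nucleus detector

The rule-based backend operationalizes "detected lymphocyte / tumor
cell": unmix the hematoxylin concentration with the (target) stain
profile, Gaussian-smooth (σ = 1 px), threshold (fixed 0.25 by default;
Otsu over tissue pixels optional), take 8-connected components, drop
components under 30 px², and classify by shape: lymphocyte if area ∈
[30, 250] px² and circularity 4πA/P² ≥ 0.7; tumor if area ≥ 300 px²;
otherwise "other". The area bands are calibrated to the generator's
geometry (lymphocyte disks ≤ ~154 px², tumor nuclei ≥ ~450 px²) with
wide margins on both sides of the decision boundaries, which is why
label recovery is exact on noiseless patches and ≥ 90 % at noise sd 8.
The fixed threshold 0.25 sits between the stroma hematoxylin response
(≈0) and the palest tumor nuclei (0.4). These parameters are
config-exposed (`DetectorParams`) and would need recalibration for real
slides with a known µm/px scale.

Class probabilities from this backend are degenerate one-hot vectors;
argmax ties anywhere in the package break toward the lowest class code.
An optional trainable backend (a small multilayer perceptron over
patches resized to its 24×24 input size) honours the same prediction
contract; it is seeded but, like any SGD-trained model, not
bit-reproducible across library versions.

## TIL score

For slides i = 1..m of a unit (m = 1 for a slide, m = #slides for a
patient):

    TIL score = Σᵢ N⁽ⁱ⁾_pos / Σᵢ (N⁽ⁱ⁾_pos + N⁽ⁱ⁾_neg)

Pooling is by summed counts, never the mean of per-slide ratios (the
discriminating case [(2,2),(0,6)] scores 0.2, not 0.25).
Other/necrotic and blank patches enter neither numerator nor
denominator. A zero denominator is an explicit `UndefinedScoreError`
(or NaN with a warning at cohort level) — silently scoring 0 would bias
cohort statistics downward.

Cohort summaries use a Gaussian KDE with Scott's-rule bandwidth on a
fixed 512-point grid over [0, 1], reporting the mode (argmax). No
boundary correction is applied, so mass near 0 or 1 leaks outside the
unit interval; for scores well inside the interval the grid integral is
1 within 1 %.

TIL maps place each patch's predicted class at its grid position
(position-keyed, order-independent); default palette red / blue / green
/ white for positive / negative / other / blank, configurable. Maps
round-trip losslessly through TSV.

## Splits and evaluation

Train/validation splits (default 8 : 2) and k-fold cross-validation are
stratified per label within each optional stratum key (e.g. cancer
type), seeded, with per-group train fractions honoured within one item.
Metrics: confusion matrix in fixed class order 0, 1, 2; accuracy;
Cohen's kappa; one-vs-rest AUC averaged over classes present in the
truth; precision, recall, specificity (TN/(TN+FP)) and F1 under both
micro and macro averaging. Micro is the default: for a single
multi-class confusion matrix micro precision = micro recall = accuracy,
the signature of published metric tables where those three coincide.
Cross-validation reports per-fold held-out metrics, their mean and sd,
and the best fold (highest accuracy, ties to the lowest index).

## Pipeline

`run_pipeline` processes slides in sorted order, isolates per-slide
failures (recorded, not fatal), and writes manifests, predictions,
scores, maps, and a run log under one output directory with a fixed
float format, so re-running with identical config and inputs reproduces
byte-identical TSVs with the rule backend. Configuration lives in one
YAML-serializable object whose defaults are the protocol values (patch
150, blank 230/15) plus the package's own Macenko and detector
defaults.

## Problem sizes used in the verification suite

Synthetic slides in tests are 4×4 to 10×10 patch grids; cohorts are 20
slides of 5×5 with 20 tissue patches each; label-recovery checks use
300 patches per noise level; the Eq.-style score oracle uses 1,000
random count lists; metric identities use 100 random confusion
matrices. These sizes give exact oracles headroom while keeping the
whole suite and the acceptance script in the tens of seconds.

## Known limitations

* Pyramidal WSI formats are not read directly; export level 0 to
  TIFF/PNG first. No magnification handling beyond the ×20 assumption.
* Detector parameters are calibrated to the synthetic geometry; real
  slides need recalibration and a real validation set.
* Per-patch Macenko estimation is skipped (pass-through) on noisy
  patches rather than replaced by a pooled slide-level estimate.
* Cells straddling patch borders are not generated, so the counting
  rule's behaviour for partial cells is untested.
* The KDE mode is grid-quantized (1/511 resolution).
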