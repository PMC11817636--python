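# Methods

## Phantom optics

The generator emulates an LED-ring multispectral dermatology camera:
per lesion it renders, at each of eight bands (414, 447, 477, 524, 671,
735, 890, 995 nm), a raw 12-bit lesion frame plus the dark frame and
neutral-gray reference frame needed for reflectance calibration.

The forward model per band λ is

    counts(i,j) = dark_offset + I(i,j) · R(i,j,λ) + ε,    ε ~ N(0, σ²)

rounded and clipped to the 12-bit range. `I(i,j)` is a smooth quadratic
illumination field (normalized maximum 1, multiplied by a per-band
amplitude that puts the brightest pixel near 90% of full scale) shared by
the lesion and neutral frames of a capture, so the flat-field division in
calibration is consequential and testable. The dark frame carries its own,
smaller noise. Renders that saturate more than 10% of pixels raise an
error (a mis-scaled illumination field).

Scene reflectance is a Beer–Lambert attenuation of a fixed background skin
spectrum on a soft lesion footprint:

    R(i,j,λ) = R_skin(λ) · exp(−s(i,j) · Σ_c conc_c · a_c(λ))

* `R_skin(λ)` rises from 0.30 at 414 nm to ~0.70 in the red/NIR (skin is
  dark in the violet, bright in the NIR).
* `a_c(λ)` is a shipped relative-absorption table for melanin
  (monotonically decaying violet→NIR), oxy- and deoxy-hemoglobin (blue/green
  peaks, deep minimum at 671 nm), and water (exactly zero at all five
  visible bands, rising steeply to 995 nm). Values are package constants
  interpolated onto arbitrary band sets; they encode qualitative shapes,
  not literature coefficients.
* `s(i,j)` is the footprint: an ellipse perturbed by low-order radial
  Fourier harmonics (border irregularity) and blurred by a Gaussian edge
  (border softness). `s ∈ [0,1]`, so absorption fades smoothly at the rim.

Chromophore concentrations are drawn uniformly from class-conditional
ranges. Three separability modes fix where the class signal lives:

* `all_bands` — melanotic melanoma (high melanin, elevated
  deoxy-hemoglobin), vascular BCC (low melanin, high oxy-hemoglobin,
  high water), intermediate nevus; every band is informative. Melanoma
  additionally gets a more irregular border (cosmetic realism).
* `nir_only` — all classes share identical melanin/hemoglobin ranges and
  differ only in water content. Because the water absorption entries are
  exactly zero below 735 nm, expected reflectance at 414–671 nm is
  class-independent *by construction*; border irregularity is also made
  class-independent in this mode so geometry cannot leak class signal into
  the visible-band arm. Water effect sizes at 890 nm exceed 10 within-class
  standard deviations, so the NIR signal is unambiguous.
* `none` — identical ranges everywhere; the negative control.

The phantom deliberately omits: radiative transfer and photon migration,
melanin depth structure, hair/artifacts, specular reflection (the emulated
device uses crossed polarizers), patient-level correlation between lesions,
and inter-device variation. Passing tests therefore demonstrate that the
pipeline extracts controlled spectral contrast — not that the classifiers
would reach any particular accuracy on clinical images.

## Calibration

`R = k(S_lesion − S_dark)/(S_neutral − S_dark)`, per band, with `k` the
known neutral-gray reflectance (default 0.5). Pixels whose denominator is
≤ 1 count are filled with the local median of valid neighbors (window grown
until filled); more than 5% such pixels in any band marks the capture
corrupt. The result is clipped to [0,1] — the learning input stays bounded
without zero-mean/unit-variance standardization, which the protocol omits
because calibrated reflectance is already normalized. Resizing to the
network side (default 128; tests use 24–32) uses area averaging (Pillow
BOX), which preserves constants and is exact for identity resizes;
calibration runs at capture resolution first, then resizes. With zero
sensor noise, calibration inverts the render model to within the bound
obtained by propagating ±0.5-count rounding through the quotient,
|ΔR| ≤ 0.5·(k + R)/(k·G − 0.5) for per-pixel gain G — asserted exactly
in the tests.

## Dataset protocol

The emulated cohort is 327 nevi / 112 melanomas / 70 BCCs. The protocol
balances by downsampling every class to the minority count (70/70/70,
n = 210), holds out a stratified 20% test set (42 cubes, 14 per class), and
partitions the remaining pool with stratified 5-fold cross-validation
(scikit-learn `StratifiedKFold`). Loss weights use the balanced scheme
`w_i = m/(C·n_i)` (scikit-learn `compute_class_weight`), which satisfies
Σ n_i·w_i = m and degenerates to unit weights on balanced data — the
balanced-subset path is the primary one; weighted training on the full
imbalanced cohort remains available via `use_class_weights`.

Augmentation applies one rigid transform per cube — rotation by a
continuous uniform angle with reflect fill plus 50/50 horizontal/vertical
flips — identically to all bands, to training folds only (augmenting
validation data showed no confirmed benefit in the emulated protocol, and
cropping/intensity jitter are excluded as counterproductive). Two modes:
streamed (a fresh transform per sample per batch; the default) and
materialized (factor−1 fixed copies appended per training cube, default
factor 50), which multiplies the optimizer steps per epoch the way a
dataset-level augmentation does.

## Architectures

Both networks are built from a declarative layer list from which parameters
are counted in closed form (conv: k^d·C_in·F + F; dense: n·u + u); the
count is asserted equal to the instantiated network's weight-array sizes.

* **2D CNN** — six SAME-padded 3×3 conv layers, filters (8,8,16,16,32,32),
  strides alternating 1/2, ReLU, no pooling, one dense softmax head. This
  reading is fixed, not configurable, because it reproduces the reference
  total of 43,123 parameters exactly (18,544 conv + 24,579 dense) on a
  128×128×8 input; adding pooling or a different filter schedule breaks
  that total. The band axis enters as input channels, so the RGB variant
  (B = 3) uses the identical layer list.
* **3D VGG-16 variant** — thirteen 3×3×3 conv layers in five blocks
  (64,64 | 128,128 | 256,256,256 | 256,256,256 | 512,512,512 — note the
  fourth block keeps 256 filters, unlike canonical VGG-16), each block
  followed by 2×2×2 ceil-mode max pooling so an 8-deep band axis survives
  all five pools (8→4→2→1→1→1); He-uniform initialization; then
  dense/dropout(0.5)/dense/dropout(0.5)/softmax. The hidden dense widths
  default to the canonical 4096/4096 but are exposed in the builder, since
  only the three-dense-layer head is fixed by the design; with the
  defaults the closed-form total on a (128,128,8,1) input is 78,558,275.

The engine behind the specs is a small NumPy implementation (im2col
convolutions, exact backprop, Adam). Every gradient path is verified
against central finite differences; forward outputs are softmax-normalized
to 1 ± 1e-5; the cross-entropy applies a 1e-7 floor inside the log.
Softmax is fused with the loss on logits during training; the standalone
`weighted_categorical_cross_entropy` is stated on normalized scores and
rejects rows that do not sum to one.

## Training protocol

The primary strategy is *continued* cross-validation: one model instance is
trained `epochs_per_fold` epochs on each successive fold's training split,
with that fold's validation split monitored (no early stopping, no
selection during the run); `fresh_per_fold` re-initializes per fold for
comparison. Adam is the default optimizer (the choice is exposed; the
protocol found optimizer choice non-critical and learning rate the only
critical hyperparameter). Runs are bit-reproducible from a single seed
(seeded init, shuffling, dropout, and augmentation). Non-finite loss aborts
with the offending fold and epoch. `random_grid_search` samples batch size
uniformly on {2..10} and learning rate log-uniformly on [1e-6, 1e-5];
model selection across a search uses final-fold validation accuracy.

`TrainConfig` accepts rates outside the search ranges deliberately: the
desk-scale profiles below use larger learning rates than the full-scale
protocol, trading fidelity for CPU-minutes.

## Evaluation

Rows of the confusion matrix are truth, columns prediction; per-class
TP/FN/FP/TN follow the one-vs-rest reading, SE = TP/(TP+FN),
SP = TN/(TN+FP), P = TP/(TP+FP), F1 = harmonic mean of SE and P. Undefined
ratios are reported as 0 and flagged `degenerate` (display rounding is 2
decimals). The malignant-vs-benign collapse sums the {melanoma, bcc} ×
{melanoma, bcc} blocks against nevus; merging classes cannot create new
errors, so binary accuracy ≥ multiclass accuracy, and totals are preserved.
Metrics are cross-checked against a brute-force per-sample recount on
1,000 random matrices. Saliency is the plain input gradient of the
top-predicted class score — absolute value, maximum over the band axis,
min-max normalized (skipped for an all-zero gradient) — chosen as the
minimal method with no dependence beyond the model at hand.

## The band-ablation experiment

`run_experiment` chains simulate → calibrate → balance → split → per band
mode (all = 8 bands; rgb = 447/524/671 nm) → train (continued) → evaluate
on the held-out test set. Both arms share the identical fold plan,
initialization seed, and augmentation stream, so the band subset is the
only varying factor — stricter than strictly necessary, but required for a
clean ablation. The report carries per-arm metrics and the accuracy gap
(all minus rgb).

## Desk-scale profile and problem sizes

The package's standard fast profile (`smoke_experiment_config`) is chosen
once as the smallest configuration in which the 2D CNN can express the
phantom's spectral contrast: 32×32×8 cubes, 70 lesions per class,
continued training over 5 folds × 3 epochs, batch 8, Adam at 1e-3,
augmentation off. Under `nir_only` phantoms the full-band arm reaches
test accuracy near 1.0 and the RGB arm stays at chance across seeds; under
`none` both arms sit at chance. The capacity check in the test suite uses
24×24 cubes, 35 lesions per class, learning rate 1e-4, and materialized
×25 augmentation for 20 epochs. The 3D VGG is exercised for construction,
forward pass, parameter-count identity, and a 2-epoch smoke train at
16×16×4 with narrowed dense layers; its full-scale training is outside the
desk profile.

## Known limitations

* The phantom's chromophore table is qualitative; absolute concentrations
  and absorption coefficients are stipulated, not estimated from tissue.
* Accuracy values obtained on phantoms say nothing quantitative about
  clinical images; only orderings and mechanisms (where the signal lives,
  what calibration recovers) transfer.
* The NumPy engine is single-threaded BLAS-bound and sized for desk-scale
  cubes; it is not a GPU training stack.
* Whether resizing should precede calibration is unspecified in the
  emulated workflow; this package calibrates at capture resolution first,
  which is the physically safer order.
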