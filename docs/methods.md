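# Methods

`tumorlens` implements a hybrid detection pipeline for grayscale
MRI-like slices: classical preprocessing, classical region proposal with
pixel-wise segmentation, handcrafted texture/shape/intensity features on
the segmented ROI, feature-level fusion with a deep-path feature vector,
and a from-scratch multilayer-perceptron (MLP) detection head. This note
records the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Preprocessing

**Min-max normalization.** Every image is rescaled to
`I' = (I - I_min) / (I_max - I_min)` so intensities span [0, 1]. The map
is rank-preserving and idempotent. A constant image has no dynamic
range; it maps to all zeros with a warning rather than raising, so blank
slices flow through batch pipelines.

**Gaussian denoising.** The 2-D Gaussian operator
`G(a,b) = exp(-(a²+b²)/(2σ²)) / (2πσ²)` is truncated to an odd window
and renormalized to unit sum — the continuous constant no longer sums to
one after truncation, and unit sum is what preserves constant images.
Defaults: σ = 1.0 pixels, 5×5 window. Borders use reflection, which
avoids dark halos at image edges; the choice is ours (any sensible
border mode would do for interior lesions). The discretized 1-D factor
attains the space–bandwidth uncertainty product Δa·Δω = 1/2 to well
under 2 % at σ = 4, size 65 (`uncertainty_product`), confirming the
discretization is faithful to the continuous operator.

**Augmentation.** One seeded random similarity + elastic transform per
call: rotation within ±15°, zoom within ±10 %, small translations,
optional horizontal/vertical flips, and a smoothed random displacement
field. The image is resampled bilinearly and the mask nearest-neighbor,
so masks stay binary. Augmentation multiplicity (copies per image) is a
config choice with default 1. All draws derive from the params seed.

## Region proposal and segmentation

Training a convolutional backbone is out of scope at desk scale. The
proposer is deterministic and classical: Gaussian smoothing → Otsu
threshold → 8-connected components with area ≥ `min_area` (default 40
px). Two scale-free guards make lesion-free slices return no proposals:
the Otsu foreground must cover < 30 % of the image (a focal lesion is a
compact bright minority), and a component's mean contrast against the
background must exceed 2× the smoothed image's global intensity spread.
Both thresholds are expressed in units invariant under per-image min-max
normalization; on default phantoms the two populations sit at ~1.6 and
~4–5 on the contrast-ratio axis and at ~0.48 vs ~0.04 foreground
fraction, so the cuts sit in wide margins. Objectness is the
contrast-to-spread ratio mapped through a numerically stable sigmoid.

The detection-loss primitives follow the standard three-term
instance-segmentation objective `L = L_cls + L_bbox + L_mask`
(cross-entropy, smooth-L1, pixelwise binary cross-entropy), with
sum-over-elements reduction by default and mean as an option, and
probability clipping at ε = 1e−12 before any logarithm. Box refinement
is the literal additive rule `b̂ = b + δ` on (row_min, col_min,
row_max, col_max); the log-scale center/size parametrization common in
detection frameworks is a drop-in alternative but is not the form
adopted here. Boxes are 0-based, half-open, row-major everywhere.

**RoI Align** divides a box into an output grid of equal bins and
averages `s × s` bilinear samples placed at regular sub-bin offsets
(`(k + 0.5)/s`), with no coordinate snapping. Array index `p` is the
center of pixel `p`, i.e. box coordinate `p + 0.5`; samples outside the
map are edge-clamped. Note that RoI Align is *defined* as this
finite-sample average: it equals the true bin integral only where the
field is locally linear, which is why its oracle tests use a linear
ramp for the dense-integration comparison and an independent bilinear
resampler at identical sample points for random maps.

**Deep-path stand-in.** The deep feature extractor contract is a
fixed-length vector per (image, box); the default implementation is RoI
Align of the smoothed image onto a 7×7 grid (D₁ = 49), flattened
row-major. A trained backbone can replace it without touching fusion.

## Handcrafted features

**GLCM texture.** Images are uniformly quantized to G = 8 gray levels
on [0, 1] (G is a package choice: small G keeps co-occurrence tables
dense on small ROIs). For each distance d ∈ {1, 2} and angle θ ∈ {0°,
45°, 90°, 135°} the co-occurrence table counts in-bounds (and in-mask)
pixel pairs at offset θ→(Δrow, Δcol): 0°:(0,d), 45°:(−d,d), 90°:(−d,0),
135°:(−d,−d), row axis down. Tables are symmetric (directional count
plus transpose — the common Haralick convention, which also stabilizes
the correlation feature) and normalized to unit sum. Four features per
table: contrast Σ(i−j)²P, correlation Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ), energy
ΣP², homogeneity ΣP/(1+(i−j)²). A single-level ROI has zero marginal
variance; correlation is then defined as 0 with a warning, so blank ROIs
flow through batch extraction instead of aborting. The feature vector
is the 32 per-(d,θ) values plus mean and range per feature (8 more),
40 in total, in a fixed documented order.

**Radiomics.** The minimal standard shape + first-order panel: area,
perimeter, eccentricity, solidity, circularity 4π·area/perimeter², and
equivalent diameter on the largest connected mask component
(8-connectivity — single-tumor framing); mean, std, min, max,
standardized skewness, excess kurtosis, and base-2 Shannon entropy of
the G = 8 quantized histogram over all masked pixels (the same G as the
texture stage, for coherence). Skewness/kurtosis are defined as 0 for a
constant ROI. Histogram percentiles are deliberately omitted.

## Fusion and the MLP head

Both vectors are z-score standardized with means/stds estimated on the
**training split only** — the standardizer refuses to fit on rows
tagged val/test (leakage guard) — and concatenated deep-part-first into
a D₁+D₂ vector with a provenance ledger (`deep`/`glcm`/`radiomics`).
The GLCM-only and deep-only ablation arms are ledger slices of the same
table, so all arms see identical inputs per seed. Constant features
standardize to 0 and are flagged.

The head is a plain feedforward stack `z = Wx + b`, ReLU hidden layers,
sigmoid (binary) or softmax (4-class) output, trained by exact
backpropagation with the update `W ← W − η ∂L/∂W` (plain gradient
descent; Adam available and used by the pipeline default). The
printed binary loss is `−[y log ŷ + (1−y) log(1−ŷ)]`; the 4-class head
uses its categorical extension. Hidden architecture, epochs, batch size
and η are open choices; defaults are (64, 32) hidden units, 300 epochs,
batch 32, η = 0.01, He-style uniform seeded initialization. Gradient
correctness is verified against central finite differences (relative
1e−5) on every layer. Ties at ŷ = 0.5 classify as the positive class.
Models serialize to a documented JSON (shapes, weights, ledger,
standardizer).

## Evaluation metrics

PSNR = 10·log₁₀(MAX²/MSE) dB, with a +inf sentinel for identical images
(serialized as the string `"inf"`). Localization accuracy = 1 −
E_d/d_max clipped to [0, 1]; the formula leaves E_d and d_max open, so
we take E_d as the Euclidean distance between predicted and true mask
centroids and d_max as the image diagonal — scale-free, in [0, 1], and
1 exactly at perfect overlap. An empty predicted mask scores 0 with a
`no_detection` flag. CPU utilization is the pure active/total time
ratio over supplied timings; no hardware sampling, since hardware
numbers are not reproducible. The classification report computes the
confusion matrix and per-class precision, recall/sensitivity,
specificity and F1 with macro averages; zero-denominator cells yield 0
and are flagged.

## Synthetic phantoms

The generator emulates a single-lesion, four-class T1-like dataset at
desk scale: a noisy slowly varying background (base 0.22, smooth field
amplitude 0.03, pixel noise σ 0.02) plus one bright lesion whose
internal texture identifies the class —

| class | texture | recipe | key signature |
|---|---|---|---|
| glioma-like | heterogeneous | base 0.62 + multiscale noise σ 0.16 | high GLCM contrast |
| meningioma-like | homogeneous | base 0.70 + smoothed noise σ 0.02 | low contrast, high homogeneity |
| pituitary-like | periodic | base 0.62 + sinusoid (period ~4 px, amp 0.18) | anisotropic contrast across angles |
| non-tumor | background-only | no lesion | empty mask |

Lesion outlines are random ellipses (axis ratio 0.6–1.0) perturbed by
low-frequency radial wobble, so boundaries are nonconvex and shape
features nontrivial. Default image size is 128×128 — chosen once for
desk-scale runtimes; all routines accept arbitrary sizes. One lesion
per image by default, matching the single-label classification framing;
a multi-lesion mode exists for the multi-proposal tests. Everything is
a pure function of (spec, class, seed): reruns are bit-identical, and
PNGs round-trip [0, 1] through 8-bit quantization.

**What passing tests do and do not show.** The phantom classes are
separated by construction in exactly the statistics the features
measure, the lesions are bright on a dark background, and noise is
Gaussian — none of which holds cleanly for real MRI (no anatomy, no
bias fields, no Rician noise, no scanner variability, no ambiguous
lesion appearance). Green pipeline properties (held-out accuracy,
ablation ordering, denoising gain, label-shuffle control) therefore
validate the *machinery* — feature correctness, leakage-free fusion,
trainable head, calibrated metrics — not clinical performance.

## Pipeline, splits, determinism

The orchestration follows the stage order preprocess → propose →
extract (GLCM + radiomics + deep stand-in) → standardize + fuse → train
→ evaluate. Segmentation runs on the denoised image; texture and
intensity features are computed on the normalized (not smoothed) image,
since the ROI's fine-scale structure is the classification signal and
smoothing is there to stabilize thresholding. When no region is
proposed, features are extracted from a centered half-size fallback box
so lesion-free slices still produce a row describing background tissue;
per-sample ROI provenance (`proposal`/`ground_truth`/`fallback`) is
recorded. A ground-truth-mask mode isolates feature/classifier behavior
from segmentation errors.

Splitting is stratified per class with round-half-up: train =
round(0.8 n), val = round(0.1 n), test = remainder — the unique simple
rule that partitions class sizes 1,426/708/930 into 2,451/307/306
(total 3,064). Membership within a class is seeded; counts depend only
on class sizes. The evaluation JSON is deterministic under a fixed
config; wall-clock timings go to a separate artifact so reruns stay
byte-identical.

Default problem sizes: 100 phantoms/class for the end-to-end property
run, 60/class × 5 seeds for the ablation comparison, 50/class for the
label-shuffle control — sizes at which the whole pipeline runs in tens
of seconds while the binomial error bars on held-out accuracy remain
informative.

## Known limitations

- The classical proposer assumes bright lesions on darker background;
  hypointense lesions would need an inverted or two-sided threshold.
- Additive box refinement (`b̂ = b + δ`) is not scale-invariant; a
  backbone plug-in would likely prefer the log-scale parametrization.
- Radiomics is 2-D, unfiltered, and not IBSI-certified; entropy depends
  on the G = 8 quantization choice.
- The deep-path stand-in is a linear resampling of the image; it is a
  contract placeholder, not a learned representation, and its ablation
  arm underperforms the handcrafted arm on phantoms by design of the
  textures.
- Correlation's 0-fallback for single-level ROIs is a convention, not a
  limit; downstream consumers should treat it as "undefined", and the
  accompanying warning says so.
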