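# tumorlens

Hybrid brain-tumor detection on grayscale MRI-like images, built as a
testable desk-scale library. The pipeline combines the two classical
ingredients of radiomics-augmented detection:

1. **Handcrafted features** from a segmented tumor ROI — gray-level
   co-occurrence (GLCM) texture statistics

   - contrast `Σ (i−j)² P(i,j)`
   - correlation `Σ (i−μᵢ)(j−μⱼ) P(i,j) / (σᵢ σⱼ)`
   - energy `Σ P(i,j)²`
   - homogeneity `Σ P(i,j) / (1 + (i−j)²)`

   over four angles and two distances, plus a standard shape and
   first-order intensity radiomics panel (13 features);
2. **Deep-path features** (D₁ = 49) extracted by sub-pixel RoI Align
   over the proposed box — a pluggable stand-in contract for a trained
   detection backbone.

Both vectors are z-score standardized on the training split only and
concatenated into a D₁+D₂ representation, then classified by a
from-scratch multilayer perceptron (`z = Wx + b`, ReLU hidden layers,
softmax head) trained by exact backpropagation (`W ← W − η ∂L/∂W`).
Region proposal at desk scale is deterministic and classical (Gaussian
smoothing → Otsu threshold → connected components), and the
instance-segmentation loss primitives (`L = L_cls + L_bbox + L_mask`,
sigmoid objectness, additive box refinement, smooth-L1, pixelwise BCE)
are implemented and unit-tested individually.

Because real patient data cannot ship with a test suite, the package
includes a first-class synthetic phantom generator: four classes
(glioma-like heterogeneous, meningioma-like homogeneous, pituitary-like
periodic, and non-tumor) whose ROI textures are separable by exactly
the statistics the features measure, with ground-truth masks and boxes,
fully deterministic under seeds. It is intended for researchers and
engineers who need a verifiable reference implementation of the
GLCM/radiomics/fusion/MLP stack, not a clinical tool.

## Worked example

```bash
python examples/train_detection_head.py
```

```
feature table: 160 samples x 102 features
fused      held-out accuracy 1.000   (val 1.000, 102 features)
glcm_only  held-out accuracy 1.000   (val 1.000, 53 features)
deep_only  held-out accuracy 0.938   (val 1.000, 49 features)

mean localization accuracy on test tumors: 0.9995
per-class recall on the test split:
  glioma-like      recall 1.00  precision 1.00
  meningioma-like  recall 1.00  precision 1.00
  non-tumor        recall 1.00  precision 1.00
  pituitary-like   recall 1.00  precision 1.00
```

The feature table holds 40 GLCM + 13 radiomic + 49 deep-path features
per phantom. The three rows compare fusion ablation arms on identical
inputs: the fused and handcrafted arms separate the four phantom
classes perfectly on the held-out split, while the deep stand-in alone
is weaker — the expected ordering, since the phantom classes differ
mainly in fine texture. Localization accuracy `1 − E_d/d_max` compares
proposal and ground-truth mask centroids against the image diagonal;
0.9995 means the proposer centers the tumor to within a fraction of a
pixel of ground truth on average.

Other examples: `generate_phantoms.py` (ground-truth structure),
`texture_features.py` (the worked 2×2 GLCM example and per-class
contrast), `segment_and_measure.py` (proposals, IoU, radiomics panel),
`denoise_and_score.py` (PSNR gain from Gaussian denoising).

A thin CLI wraps the same library calls:

```bash
tumorlens generate --out data/ --n-per-class 25 --seed 1
tumorlens split data/manifest.csv
tumorlens run --seed 1 --out run/
tumorlens evaluate run/model.json data/glioma-like_0000.png
```

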