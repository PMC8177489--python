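# Methods

## Problem and model

The package classifies en-face scanning-laser-ophthalmoscopy (SLO) images of
the optic nerve head (ONH) into glaucoma patients versus healthy controls in
a low-data regime (a few hundred images), and benchmarks the image
classifier against the established structural biomarker — retinal nerve
fiber layer (RNFL) thickness — and against hand-crafted image features.

The image classifier is a deliberately compact convolutional network.  Input
is a 156×238×1 region of interest cropped around the ONH from the 496×496
instrument frame and min–max normalized per image to [0, 1].  The network
has three blocks of 3, 2 and 2 stride-1 same-padded convolutions (each
followed by batch normalization and ReLU); each block is preceded by a 2×2
average pooling and followed by a 2×2 max pooling.  The head is a 128-unit
fully connected layer with ReLU, dropout at rate 0.60, and a 2-unit softmax.
Training uses Adam at learning rate 0.001, two-class cross-entropy,
Glorot-uniform kernel initialization with zero biases, up to 250 epochs, and
checkpoints the epoch with the highest validation accuracy (ties resolved
toward the earlier epoch).

### Cross-validation ensemble

For outer fold f of a stratified k-fold split, the training fold is divided
into k−1 equal parts; base model i trains on k−2 parts and validates on part
i, so the k−1 base models see slightly different data.  Their outputs on the
held-out fold are combined by one of four rules:

* **majority voting** (`mv regular`) — most-voted class;
* **weighted majority voting** (`mv weighted`) — votes weighted by each base
  model's validation balanced accuracy, normalized to sum to one;
* **support accumulation** (`sa regular`) — argmax of the summed class
  probability pairs;
* **weighted support accumulation** (`sa weighted`) — argmax of the
  weighted sum.

Ties (possible with an even number of voters or constructed support
weights) fall back to unweighted support accumulation and, if still tied,
predict control.  The "single model" reference is the mean over the k−1
base models of each fold.  Evaluation is balanced accuracy — the mean of
sensitivity (glaucoma positive) and specificity — with per-fold scores
compared across methods by a two-sided paired Wilcoxon signed-rank test at
α = 0.05 (exact null distribution at these fold counts; zero differences
dropped, with Pratt handling available; identical score sequences report
p = 1).  No multiple-testing correction is applied across pairs.

### Design choices in open territory

* **Filter counts** per block are not pinned by the architecture's source
  figure; the default 8/16/32 (3×3 kernels, 2×2 pools) keeps the model in
  the intended low-parameter regime and is fully configurable.
* **"Binary cross entropy" with a 2-unit softmax** is implemented as
  two-class categorical cross-entropy on integer targets — mathematically
  identical.
* **Batch size** (unstated upstream) defaults to 16; the scaled-down
  experiments use 8 so that small inner training folds still provide several
  gradient updates per epoch.
* **Outer folds are stratified by class**: with 122/105 cohort sizes,
  unstratified folds risk single-class validation parts.
* **Weight metric** for weighted combining is validation balanced accuracy
  (plain accuracy available by configuration).
* **Augmentation** — independent horizontal/vertical flips (p = 0.5 each),
  shifts uniform in ±0.15 of the frame, rotations uniform in ±50°, bilinear
  interpolation, nearest-neighbour border fill, clamped to [0, 1] — is
  training-time only and resampled every epoch; validation and test images
  are never augmented.  Normalization is per image.
* **Per-fold seeds** are derived deterministically from the experiment seed,
  so folds are decoupled but reproducible.

## The neural-network engine

No deep-learning framework is part of the package's dependency set; the
layers (im2col convolution, batch normalization, average/max pooling, dense,
inverted dropout), the softmax cross-entropy loss and the Adam optimizer are
implemented in NumPy (float64, NHWC layout) and verified against central
finite differences in the test suite.  Batch-normalization running
statistics use bias-corrected exponential moving averages (momentum 0.9) so
inference is usable after few updates — relevant when an inner training
fold yields only a handful of batches per epoch.  Max-pooling routes
gradients to the first window maximum; odd spatial dimensions are floored.

The inception-style benchmark model keeps the comparison's intent — a much
larger general-purpose backbone finished by new fully connected layers of
sizes 128 and 2 — using a stem convolution plus three parallel-branch
modules (1×1, 1×1→3×3, 1×1→3×3→3×3, and 3×3-average-pool→1×1 branches,
concatenated) between pooling stages, then global average pooling.  It is a
reduced inception-style topology, not a layer-for-layer inception v3: a
~24M-parameter backbone is neither trainable at this package's problem
sizes nor shippable with pretrained weights, so `pretrained=True` raises
and random initialization is the supported path.  Its parameter count
remains well above the task-specific CNN's, preserving the compact-vs-large
comparison.

## Baseline classifiers

* **RNFL**: MLP (one hidden layer of 100 units, ≤1000 iterations), kNN
  (k = 5, Euclidean), RBF-kernel SVM, CART and Gaussian naive Bayes on the
  seven thickness values (average + six sectors), standardized per training
  fold; scikit-learn estimators behind the module surface.
* **Image features + SVM**: whole image flattened (156·238 values);
  row/column means (156+238 = 394 values); GLCM contrast and dissimilarity
  (32 gray levels, distance 1 px, angles 0°/45°/90°/135°, symmetric
  normalized matrix, features averaged over angles); PCA retaining 99%
  explained variance, fitted on the training fold only; and GLCM+PCA
  concatenated.  GLCM and PCA features are standardized per training fold;
  raw-intensity vectors are not, since they already share the [0, 1] scale
  and per-pixel standardization mainly amplifies background noise.

## Synthetic data

The clinical dataset (227 subjects: 122 controls, 105 glaucoma) is not
public, so the generators emulate its two modalities.

**Images.** A bright elliptical disc (rim intensity = background + rim
contrast) with a brighter concentric cup, dark random-walk vessel polylines
radiating from the disc centre, multiplicative speckle and additive Gaussian
noise, clipped to [0, 1].  The class effect enters only through the
cup-to-disc ratio (default 0.35 control vs 0.65 glaucoma, matching clinical
ranges) and optionally rim contrast, so separability is one dial.  Geometry
is resampled internally until valid (cup strictly inside disc).  Named
presets fix the study conditions used by the tests and the acceptance
script: *high effect* (cup-to-disc 0.30 vs 0.75, noise SD 0.02), *moderate
effect* (0.40 vs 0.52, noise SD 0.08) and *null* (identical geometry for
both classes — the configuration under which no classifier can beat chance
in expectation).  What the generator does **not** reproduce: real SLO
texture, vessel branching anatomy, illumination gradients, or off-centre
discs; passing tests therefore demonstrate that the pipeline recovers known
structure and stays honest under the null, not clinical-grade performance.

**Thickness tables.** Per group, the seven RNFL values are drawn from a
multivariate normal whose marginals default to the published cohort
statistics (e.g. average RNFL 97 ± 8 µm control, 62 ± 12 µm glaucoma) with a
uniform inter-sector correlation (default 0.6 — only marginals are
published), truncated below at 1 µm for physical plausibility.  The printed
group separation on the average alone is ≈3 pooled SDs, so these tables are
close to separable; multivariate-normal draws lack the outliers and
measurement artifacts of instrument data.

## Problem sizes for the shipped experiments

The test suite and the acceptance script run the CNN experiments at reduced
scale, a deliberate package choice: 64×80 px images, 40 per class, filter
counts 4/8/16 with a 32-unit head, batch size 8, 30 training epochs for the
high-effect run and 15 for the 10-seed moderate-effect sweep, and k = 5.
Null-safety runs use 20 images per class at 2-fold cross-validation with 5
epochs.  Fold-plan and metric checks run at the full 227-subject layout,
which is cheap.  The full-size architecture (156×238, 8/16/32 filters,
128-unit head, 250 epochs) is exercised for construction and contract tests
and available through the CLI.

## Numerical notes and limitations

* Probability pairs from the softmax sum to 1 within 1e−6; balanced accuracy
  equals (sensitivity+specificity)/2 to 1e−12 by construction.
* Sensitivity/specificity raise a named error when their denominator is
  empty rather than returning NaN.
* Determinism: generators, fold plans and training are reproducible given
  (config, seed) on a fixed NumPy backend; augmentation draws come from the
  training RNG stream.
* The Wilcoxon exact distribution assumes no ties among non-zero
  differences; with coarse per-fold scores ties can occur and scipy's
  tie-corrected approximation takes over.
* Balanced accuracies from small test folds (22–46 samples) are coarse;
  fold-to-fold SDs at these sizes are dominated by counting noise, matching
  the high SDs typical of low-data studies.
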