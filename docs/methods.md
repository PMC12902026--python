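# Methods

This note documents the models and procedures implemented in `sicklenet`,
the parameter defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Synthetic smear generation

Each image is a field of view: a stained background (pale eosin tint,
smooth two-way sinusoidal illumination gradient, per-image brightness
offset, additive Gaussian pixel noise) with cells placed by rejection
sampling under a bounded-overlap constraint (at most 100 placement attempts
per cell; impossible packings raise an error rather than silently dropping
cells).

Normal erythrocytes are filled discs. Sickle cells start from an ellipse
with semi-axes (s, 0.75 s) and have a disc of radius s subtracted, centred
at distance 2s − c·s along the minor axis, where c ≥ 0 is a single
continuous "curvature" knob: at c = 0 the cutting disc does not touch the
ellipse (plain elliptical footprint) and increasing c slides it in
continuously, carving a crescent. At c = 1 the footprint's solidity
(area / convex-hull area) falls below 0.78, well separated from a disc's
~0.93. An image is labelled *sickle* iff it contains at least one sickle
cell, matching image-level labelling of real thin-film datasets; the union
of sickle-cell footprints is stored as a mask for evaluating saliency maps.

Class imbalance is a free parameter of `generate_dataset` (e.g. the
1185 : 800 normal-to-sickle ratio of real screening data); sickle-class
images mix crescent and round cells (60 % crescents by default) because
sickled and normal erythrocytes co-occur in real fields of view. Generation
is bit-reproducible: per-image seeds are spawned from the master seed via
`numpy.random.SeedSequence`.

The `separable` preset (illumination ±1 grey level, gradient amplitude 2,
colour jitter σ = 2, pixel noise σ = 1.5, curvature 1.3) realises the
minimal-nuisance regime used by the desk-scale experiments: classes are
separated in pixel space by construction. What the generator does *not*
emulate: overlapping/occluding cell clumps, staining artefacts and debris,
focus variation and depth-of-field effects, camera noise statistics, or the
full morphological continuum between discocytes and sickled forms. Passing
the end-to-end tests therefore demonstrates that the pipeline's mechanics
(mining, optimization, embedding classification, saliency) work as
specified — not that the accuracy figures transfer to real blood films.

## Quality filtering

Two per-image scores: mean HSV brightness (V = max(R,G,B), range 0–255) and
a zoom proxy, the filled area of the largest connected foreground region
after grayscale conversion, Gaussian blur (5×5-equivalent kernel) and
binarization (Otsu by default; a fixed threshold is available since
adaptive-vs-fixed is a free choice). Cells are darker than the stained
background, so foreground = below threshold. Images whose blurred grayscale
dynamic range is below 0.15 (on [0,1]) are treated as contour-free and
score 0 — Otsu on a near-uniform noisy background would otherwise bisect
the noise and report a spurious half-canvas contour; genuine cell-bearing
images have ~0.3 contrast and clear the floor comfortably.

Scores are min-max normalized *within the batch being filtered* (train and
test batches independently), combined as w_b·brightness + w_z·zoom with
w_b = w_z = 0.5 by default (the weighting is a free parameter), and the
top N per class are retained, ties broken by image id for determinism.
A constant-score batch maps to all zeros rather than erroring. Selection is
invariant under any order-preserving rescaling of the raw scores.

## Embedding network

The runnable backbone, `tinycnn`, is three conv(3×3)/ReLU/maxpool blocks
with 16, 32 and 64 filters (≈32k parameters), implemented directly on NumPy
arrays with hand-written backpropagation (`sicklenet.nn`); every layer's
backward pass is validated against finite differences in the tests. On top
of the backbone: global average pooling, batch normalization, dropout
(rate 0.2), then the output head — Dense→128 with ReLU for embedding mode
(all components non-negative) or Dense→1 with sigmoid for probability mode.
BatchNorm precedes Dropout so its running statistics are estimated on
noise-free activations. Embeddings are not L2-normalized; nothing in the
training objective assumes unit norm, and the classifiers are
translation/rotation equivariant either way. Inputs are bilinearly resized
to 64×64 and scaled to [0,1]. All layers are trainable; nothing is frozen.

ImageNet backbones (ResNet-50, DenseNet-121, EfficientNet-B0, MobileNetV2)
are recognised names but need a pretrained-model backend this package does
not bundle; requesting one raises `NotImplementedError`. The pipeline's
logic is backbone-agnostic — every stage interacts with the model only
through the embedding/probability contract.

## Objectives

Distances are squared Euclidean throughout; the margin m (default 0.2,
configurable) doubles as the semi-hard inequality's α. Mining is online per
mini-batch and enumerates *exactly* the label-valid triplets with
d(A,P) < d(A,N) < d(A,P) + m (strict inequalities, deterministic (a,p,n)
ascending order); a single-class batch yields an empty list as a signal,
and a batch with no mined triplets contributes zero loss. The batch
objective is the mean triplet loss over the mined set. Note a structural
property: each mined triplet's loss lies in (0, m), so the mined-set mean
hovers near m/2 while any semi-hard negatives remain and reaches 0 only
when batches stop yielding triplets — the mined count, not the mean alone,
indicates embedding quality.

Focal loss uses the standard modulating factor (1 − p_t)^γ with p_t = y_p
if y = 1 else 1 − y_p, defaults α = 0.25, γ = 2. A published variant writes
the factor as (1 − y)^r in terms of the true label, which zeroes the loss
on every positive sample for r > 0 — a degenerate objective incompatible
with both the γ = 0 → BCE reduction and the class-imbalance motivation, so
the p_t form is implemented. Predicted probabilities are clamped to
[1e−7, 1 − 1e−7] so losses are always finite. Training differentiates the
losses analytically with respect to the logit (BCE: y_p − y) or the
embeddings (per-triplet: 2[(a−p) − (a−n)] on the anchor, −2(a−p), +2(a−n)
on positive/negative); all gradients are finite-difference-checked.

## Training protocol

Adam, initial learning rate 1e−4; batch size 16 for triplet training and 32
for BCE/focal. Triplet batches are drawn class-balanced (8 + 8) — without
both classes in a batch no triplet exists. The dataset is split 80/20
stratified (validation gets floor(0.2·n) per class, remainder to train;
deterministic given the seed). Focal runs decay the learning rate by 0.2
after 3 consecutive epochs without validation-loss improvement (floor
1e−7); triplet and BCE runs keep it static. Validation accuracy during
triplet training uses a class-centroid classifier fitted on the current
training-fold embeddings, since a metric-learning model has no probability
output of its own. Training is pure NumPy arithmetic and therefore exactly
reproducible from the seed.

The desk-scale experiment size — 60 training and 30 test images per class,
10 epochs, medians over 3 seeds — keeps a full three-loss, three-seed grid
within a few CPU-minutes while leaving enough optimizer steps for the loss
trends to be visible.

## Classifiers

Centroid: μ_c is the arithmetic mean of class-c training embeddings;
prediction is argmin_c ‖z − μ_c‖₂ with exact ties to class 0. KNN (default
k = 5) stores raw embeddings (no tree index; N is small in this regime),
ranks by Euclidean distance with distance ties broken by stored index
(stable sort), and takes the majority vote; a vote tie — impossible for odd
k in a binary problem — falls back to the nearest neighbour's label. The
squared distance is compared internally since argmin is unchanged under the
monotone square. For probability-head models the back-end classifiers use
the penultimate (post-batch-norm) representation, the last layer before the
classification head.

## Grad-CAM

Channel weights are spatial means of the class-score gradients at the last
convolutional layer; the map is ReLU(Σ_k α_k A^k), bilinearly upsampled to
input resolution, hence non-negative everywhere. For probability-head
models the pre-sigmoid logit is differentiated (negated for class 0). For
embedding models the class score is centroid-based; two rules are provided.
The plain score −‖z − μ_c‖² has a gradient that vanishes exactly when an
image is confidently classified (z → μ_c), which in practice yields empty,
noise-dominated maps on the very images one wants to explain. The default
is therefore the class-contrastive score ‖z − μ_other‖² − ‖z − μ_c‖², whose
gradient 2(μ_c − μ_other) never vanishes and whose argmax over classes
coincides with the centroid classifier's prediction; the plain rule remains
available via `score="centroid"`. Overlays min-max scale the map per image,
colormap it and alpha-blend onto the original.

## Evaluation

Positive class is *sickle* (label 1). Accuracy, precision, recall and F1
are computed from confusion counts; zero-denominator precision/recall are
defined as 0 with a warning so degenerate grids complete rather than abort;
F1 is 0 when precision + recall = 0. Reported tables round to 3 decimals.
The experiment grid runs every backbone × loss combination, records
failures per row and continues, and emits results in the column order
network, loss, epoch, batch_size, learn_rate, val_accuracy, test_accuracy,
precision, recall, f1.

## Known limitations

- Only the `tinycnn` backbone is trainable here; conclusions about
  ImageNet-pretrained backbones cannot be drawn from this package alone.
- The synthetic generator's simplifications (listed above) mean measured
  accuracies characterise the pipeline, not clinical performance.
- The mined-set triplet loss is not a monotone progress metric (see
  Objectives); training curves should be read together with validation
  accuracy.
- KNN prediction is O(N) per query; adequate for the dataset sizes used,
  not for large galleries.
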