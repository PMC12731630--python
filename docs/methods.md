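# Methods

## The model

The classifier is a vision transformer (ViT) with shallow heads. An
H×W×C image is cut into non-overlapping P×P patches (N = H·W/P²),
linearly embedded, given learned position embeddings, and passed through
pre-norm transformer blocks; the output tokens reshaped onto the patch
grid form the feature map f ∈ R^{D×(H/P)×(W/P)}. Global average pooling
over the grid gives GAP(f) ∈ R^D, a projector MLP maps it to m, and a
classifier MLP maps m to logits z ∈ R^K. At full scale
(H=W=224, P=16, D=768) the grid is 14×14 and m ∈ R^192 with K=5; the
desk-scale variant (32–64 px images, D=64, depth 2) has the identical
block structure and is what every experiment in the test suite runs.

Initialization: the patch embedding (a strided convolution expressed as
a linear map on flattened patches) is Kaiming-normal; all other linear
layers are Xavier-uniform; normalization layers start at scale 1 /
shift 0. Builds are reproducible under a seed, with independent streams
per component so the baseline and the two-stage pipeline share head
initialization exactly.

## The two training stages

**Stage 1 — class-weighted supervised contrastive pretraining.** Batches
are built as two independent augmentations of each sampled image, so
every anchor has at least its sibling view as a positive. The encoder
output is pooled, passed through a throwaway 2-layer contrastive head,
L2-normalized, and scored with the class-weighted supervised contrastive
loss. Class weights are inverse class frequencies normalized to mean 1,
computed from the *training split only*; each anchor term is scaled by
w_{y_i}/w̄ where w̄ is the batch mean of per-sample weights, taken
literally over all batch members (this per-batch renormalization is
redundant in expectation with the mean-1 class normalization, but not
per batch; we keep both as defined). After pretraining the contrastive
head is discarded.

**Stage 2 — frozen-encoder head training.** The encoder is frozen
(bit-exact, asserted by parameter checksums), its pooled features are
cached once, and projector + classifier are trained with unweighted
cross-entropy. Features are cached *un-augmented*: with a frozen encoder
and shallow heads, augmentation adds little while forcing a full encoder
forward per step; the cache makes stage 2 roughly two orders of
magnitude cheaper. The supervised baseline runs stage 2 on a freshly
initialized encoder (frozen by default, so the only difference from the
two-stage pipeline is the pretraining objective; a fine-tune switch
covers the other reading of a "trained with SL" baseline).

Both stages use AdamW (decoupled weight decay), constant learning rate
3e−4, weight decay 1e−4, temperature 0.07, at most 50 epochs, and
validation-loss early stopping with patience 5 and best-epoch weight
restoration. Validation contrastive loss is computed on two-view batches
drawn with a fixed per-run seed so successive epochs are compared on
identical batches. Ties in the best-epoch argmin break to the earliest
epoch.

### Loss conventions and degenerate cases

- Embeddings entering either contrastive loss are L2-normalized (the
  `EmbeddingBatch` constructor and the differentiable training path both
  normalize); similarities are plain inner products of unit vectors.
- Anchors without positives contribute nothing and are excluded from the
  averaging denominator — their term is undefined at |P(i)| = 0. A batch
  in which *no* anchor has a positive raises a degenerate-batch error.
  Two-view batch construction guarantees this never happens in training.
- The log-sum-exp over the contrast set is stabilized by subtracting the
  per-anchor masked maximum; self-similarity is excluded by masking, not
  by large negative constants, so the vectorized loss agrees with the
  literal triple-loop oracle to ~1e−6 in float64.
- The loop oracle (`supcon_loss_oracle`) is a deliberately naive
  transcription of the definitions kept only for tests; it shares no
  code with the vectorized path.

## Data pipeline

Preprocessing is bicubic resize (Keys a=−0.5 kernel, via Pillow) to the
model's input size, then per-image Z-standardization over all pixels and
channels; zero-variance images map to zeros. Per-image (rather than
dataset-level) statistics were chosen for streaming simplicity and
recorded here as a deliberate choice. The 8:1:1 split is stratified per
class with floor rounding (train filled first) so small validation/test
splits contain all classes; a global-floor unstratified mode is also
provided — on 6323 items it yields 5058 training images, while per-class
flooring yields 5056. Augmentations are 90° rotations, horizontal and
vertical flips, brightness/contrast jitter (±20%), Gaussian blur
(σ ∈ [0.1, 1.0]) and additive Gaussian noise (σ = 0.05 in normalized
units); magnitudes are configurable defaults, each applied independently
with probability ½ (rotation always draws k ∈ {0..3}).

## Synthetic data

The generator emulates B-mode speckle: each image is a Rayleigh
speckle field, Gaussian-smoothed at a class-dependent sigma (texture
coarsening with stage), scaled by a class gain, plus a class-dependent
count of bright oriented bands mimicking septa-like echogenic streaks;
the class-count profile follows the 2114/861/793/857/1698 imbalance of
the motivating five-stage dataset. A single `separation ∈ [0, 1]` knob
scales the inter-class spread of gain, smoothing and band count;
separation 0 makes the classes exchangeable. The medium fixture (1000
images, 64×64, separation 0.7) is the stated world of the scaled-down
comparison experiment.

What the generator does **not** model: point-spread-function convolution
of scatterer fields, attenuation/TGC artefacts, probe or patient
variability, or any claim of METAVIR-like appearance. A green comparison
test therefore establishes that class-weighted contrastive pretraining
extracts class structure better than supervised heads on a random
encoder *under this texture model* — it does not certify clinical
performance.

## Quantized evaluation

FP32 is the identity. FP16 casts parameters and activations to half
precision inside every linear layer (surrounding elementwise ops inherit
the dtype). INT8 applies dynamic per-tensor affine fake-quantization
(8-bit, round-to-nearest) to the weights and input activations of linear
layers only, computing the matmul in float — the standard CPU
post-training dynamic-quantization contract; the patch-embedding and
normalization layers stay in float. Quantized modes are inference-only.

## Metrics

Predictions are the probability-row argmax with ties to the lowest class
index. Precision/recall/F1 are support-weighted one-vs-rest averages
(weighted recall is algebraically identical to accuracy, asserted in the
report type); AUROC is the per-class one-vs-rest rank statistic with 0.5
tie credit (trapezoidal), and mAUROC its unweighted mean, reported
unrounded. Classes absent from the evaluated labels have undefined AUROC
and are dropped from the mean with a warning. Metric computation is
delegated to scikit-learn; the tests check it against hand-computed
confusion-matrix and Mann–Whitney oracles. ROC export writes one point
per distinct threshold plus the (0, 0) anchor sklearn prepends.

## Numerical and scale choices

- The whole stack runs on a small NumPy reverse-mode autograd engine
  (float32 training, float64 loss verification); gradients are verified
  against central differences for every layer type.
- The desk-scale comparison experiment uses a 64×64 input with 16-pixel
  patches (4×4 token grid, as in the 32/8 tiny default) to keep five
  seeded end-to-end runs within a few CPU-minutes; depth 2, width 64.
- Stage-2 head training on cached features makes `learning_rate = 0` an
  exact no-op, which the tests use as a freeze witness.
- Loading published pretrained ViT-base weights is not supported: the
  package is NumPy-only and evaluation environments are offline. The
  full-scale configuration is exercised as a shape/arithmetic contract.

## Known limitations

- No learning-rate schedule (constant η) and no mixed-precision or
  distributed training.
- The stage-2 epoch budget reuses the stage-1 recipe (max 50, patience
  5); the two stages are tuned jointly by the published values, not by
  any search in this package.
- FP16/INT8 simulation reproduces the numerics of reduced precision, not
  its speed; everything executes in NumPy.
- Synthetic imagery is a texture stand-in (see above); conclusions about
  real ultrasound require real data through `load_dataset`.
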