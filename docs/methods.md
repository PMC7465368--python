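# Methods

## Model

The classifier is a densely connected convolutional network over 224 × 224 × 3
patches. The stem zero-pads to 230 × 230, applies a bias-free 7 × 7 stride-2
convolution to 64 channels (112 × 112), batch normalization, ReLU, and a 3 × 3
stride-2 max pool with 1-px padding (56 × 56). Four dense blocks follow with
layer counts 6/12/48/32 at the full depth; each dense layer is the composite
BN → ReLU → 1 × 1 conv (to the bottleneck width, 4 × growth = 128) → BN → ReLU
→ 3 × 3 conv (growth = 32 new channels), concatenated onto its input. Between
blocks a transition (BN → ReLU → 1 × 1 conv halving the channels → 2 × 2
stride-2 average pool) compresses the representation; a final BN + ReLU closes
the last block. Channel widths therefore follow
64 → 256 → 128 → 512 → 256 → 1792 → 896 → 1920.

A global-average-pool tap can be attached after each stage; with all four taps
the pooled widths are 128, 256, 896 and 1920 and their concatenation is the
3200-feature fused descriptor. The head is dropout (default rate 0.5) → BN →
dense softmax. Multi-scale input is realized by pooling the 16 patches of one
image (4 pyramid scales × 4 quadrants) as independent 3-channel samples: the
stem convolution's 9408 = 7·7·3·64 parameters fix a 3-channel input, so the
"concatenation" of scales happens in the sample dimension, not the channel
dimension.

### Parameter accounting

The ledger counts convolutions bias-free and every normalization layer at
4 parameters per channel — scale and shift plus the two tracked batch
statistics, i.e. the sum of what a framework reports as trainable and
non-trainable. One dense layer on `c` input channels costs
`4c + 128c + 512 + 9·128·32 = 132c + 37,376`; a transition on `c` channels
costs `c(c/2 + 4)`; the last dense block includes its trailing normalization
(4 × 1920 = 7,680). Under this convention the closed-form ledger and the
constructed network agree exactly, stage by stage and in total (18,360,392
for the 8-class full-depth spec), and the test suite verifies the agreement
for all 15 non-empty tap subsets.

### Tap subsets and ablation semantics

For a tap subset T the backbone is built up to block max(T) (feature-map
ablation removes trailing depth blocks, mirroring contiguous depth-block
studies); taps 1–3 pool the corresponding transition outputs, tap 4 the final
normalized block output. The single-tap baseline configuration ("taps = {4}")
keeps the full backbone and classifies from the 1920-wide final GAP alone.

## Numerical kernel

No deep-learning framework is a dependency; `histofuse.nn` implements the
layers in numpy. Convolutions run through a channel-first im2col and BLAS
matmuls; input gradients use the transposed-convolution identity through the
same im2col path. Batch normalization uses batch statistics in training and
tracked running statistics (momentum 0.9, eps 1e-5) at inference. Dropout is
inverted (identity at inference). Weights initialize He-normal for
convolutions, Glorot-uniform for the dense head, from the model seed. The six
optimizers (SGD, RMSprop, Adadelta, Adam, Adamax, Nadam) follow the common
Keras update rules with eps 1e-7. Every layer's backward pass is verified
against central finite differences in float64; training runs in float32.

## Preprocessing

Stain normalization defaults to Reinhard-style mean/variance matching in the
Ruderman lαβ space: RGB → LMS → log10 → lαβ, each channel shifted/scaled to a
reference mean/std, then inverted and clipped to the valid range. The bundled
default reference corresponds to a typical well-stained H&E field; any
`StainStats.from_image` reference can be substituted. A Macenko-style mode
(optical-density SVD plane, 1st/99th angle percentiles, reference H/E vectors
and 99th-percentile concentration matching) is available behind
`method="macenko"`. Normalization happens before rescaling.

Pyramid levels are `round(ratio × side)` with bilinear Pillow resampling
(half-pixel centers); the ratio list is taken literally as (1, 0.5, 0.33,
0.25) — 0.33 is not 1/3, which is immaterial after the final resize but fixed
for reproducibility. Quadrants are the 2 × 2 grid of `floor(side/2)` crops in
row-major order; odd trailing rows/columns are dropped. Inputs whose smallest
pyramid level would fall under 8 px are rejected.

## Augmentation

Horizontal/vertical flips (p = 0.5 each), rotation up to ±30°, width/height
shifts up to ±10%, brightness in [0.8, 1.2], zoom ±10%, Gaussian blur with
σ ∈ [0, 1] px. Rotation, zoom and shift are composed into a single bilinear
affine transform with reflection fill, keeping the patch size unchanged. The
ranges are not dictated by the protocol, which names only the transform
families; these defaults reflect common histology practice ("slight" blur)
and are all exposed in the config. Augmentation is applied on the fly per
epoch; materializing an augmented dataset is possible by saving augmented
patches but is not the default.

## Training protocol

Patch-wise cross-entropy on one-hot labels; every patch inherits its source
image's label. Defaults follow the selected configuration: Adam, learning
rate 1e-4, batch size 32, dropout 0.5, 64 epochs for the augmented scenario.
(The printed configuration table lists an optimizer name in its batch-size
row — an apparent typesetting slip — so batch size falls back to 32 from the
assessed grid; the table's epoch values 32/64 take precedence over the grid's
30/40/50/70 as the selected values.) `binary_cross_entropy` on a two-class
softmax head is handled by the same categorical path, to which it is
equivalent for one-hot targets. Class imbalance is uncorrected by default;
inverse-frequency class weights sit behind `class_weights=True`.

Hyperparameter selection uses 5-fold cross-validation with folds
patient-disjoint whenever patient ids exist (the clinically defensible
reading of patient-wise separation; image-disjoint otherwise), choosing the
highest mean validation patch accuracy. Reported metrics are means over
`trials` (default 5) independently seeded runs via `repeated_trials`.

Train/test splitting shuffles patients with the run seed and moves whole
patients into the training side until the image fraction reaches the target
ratio; the last patient added may overshoot the 70% boundary by one patient's
worth of images, which is documented rather than corrected. ICIAR-style data
carries no patient metadata and splits at image level; a pre-split directory
pair can be scanned separately to honor a published train/test division.

## Fusion and evaluation

Majority voting takes the modal per-patch argmax label; maximum voting the
label of the single highest patch probability; sum voting the argmax of the
summed vectors. Every tie — including per-patch argmax ties and equal top
probabilities inside maximum voting — resolves to the earliest class in the
malignancy priority (BreakHis: DC, LC, MC, PC, A, F, TA, PT; ICIAR: Invasive,
InSitu, Benign, Normal), so ambiguity never favors the benign side.
Sensitivity and specificity are one-vs-rest; a class absent from both label
sequences yields NaN, never a silent zero.

The paired-model comparison is McNemar's test with Edwards' continuity
correction, `(|n12 − n21| − 1)² / (n12 + n21)` against chi-square with one
degree of freedom. This is the variant whose p-values match the published
two-model comparison tables (0.39 and 0.08), which fixes the convention; the
implementation is cross-checked against statsmodels in the test suite.

## Synthetic data

The generator emulates the two directory layouts with Poisson-scattered
Gaussian "nuclei" on a tinted, speckled background. Class `i` draws
`Poisson(60 + 180·i)` blobs per image with radii uniform in
`[4, 10] × 0.65^i` — denser, smaller nuclei for higher classes, the direction
real tumor grades take — on a class-specific tint cycled through
eosin-pink-to-hematoxylin-purple values; a ±6% per-image channel gain jitter
emulates staining variability and gives normalization something to remove.
Adjacent classes are separated by far more than three Poisson standard
deviations in blob count, and a logistic model on per-patch first-order
statistics already classifies raw default-size textures at ≥90%, so
end-to-end training checks exercise the pipeline rather than a hard
recognition problem. Default conditions: BreakHis layout, 2 classes (one
benign subtype A, one malignant DC), 4 patients per class, 3 images per
patient, 700 × 460 px at a nominal 200× magnification.

What the toy textures do **not** capture: real nuclear morphology and
chromatin texture, tissue architecture (glands, stroma), scanner noise,
inter-patient biological variability beyond tint/count jitter, and class
overlap. Passing the desk-scale checks therefore demonstrates that the
pipeline is wired correctly end to end — not that the model reaches any
particular accuracy on real histopathology.

## Desk-scale study conditions

The end-to-end training check uses the default synthetic dataset above with
a reduced-depth backbone (block repeats 2/2/4/2, growth 32, all four taps,
fused width 384) trained for 5 epochs with Adam at learning rate 1e-3, batch
16, dropout 0.5, augmentation on — about 290 training patches, chosen so the
whole run finishes in minutes on a single CPU while leaving the architecture
topology intact. The learning rate is 1e-3 rather than the full-scale 1e-4
because the tiny dataset affords larger steps within the epoch budget. Under
these conditions the run reaches 100% patch-wise training accuracy and 100%
image-wise accuracy under maximum voting (the test asserts ≥90%). Unit tests
use a further miniaturized spec (input side 32, growth 8, repeats 1/1/1/1)
whose ledger/backbone agreement is checked by the same machinery.

## Known limitations

- Full-scale replication (the published accuracy tables on BreakHis/ICIAR)
  requires the external datasets and GPU-scale training and is out of scope;
  the numpy kernel is single-threaded-CPU oriented.
- Pretrained (ImageNet) initialization is accepted as an option token but not
  shipped, since it would require downloading external weights.
- The 210-layer depth preset has no published layer allocation; the shipped
  presets are the 201-layer backbone and the 205 = 201 + 4-layer fusion-head
  default.
- Percentage columns of the parameter ledger are reported to one decimal and
  only their ~100 sum is asserted, since printed roundings are inconsistent.
- Maximum voting is sensitive to a single overconfident patch by design;
  sum voting is the robust alternative when calibrating on noisy data.
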