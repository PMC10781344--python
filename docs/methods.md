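# Methods

## Model

mid-DeepLabv3+ is an encoder–decoder segmentation CNN for plated-food
images. Input is an RGB batch (N, H, W, 3) with H, W divisible by 16;
output is a logits map (N, H, W, K). Softmax is applied only in the loss
and at prediction time.

### Backbone

A reduced ResNet50: the 7×7/2 stem with 3×3/2 max-pool, then bottleneck
stages conv2 (3 blocks, width 64), conv3 (4 blocks, 128) and conv4
(6 blocks, 256); conv5 is removed. Stage downsampling (stride 2) sits on
the first 1×1 convolution and the projection shortcut of the first block
of conv3/conv4, and the stem uses explicit symmetric padding then valid
convolution — the layout of the canonical Keras ResNet50, whose weight
shapes this backbone mirrors exactly (including biases on all backbone
convolutions). Three activations are exported:

| tap    | position                                            | stride | ch  |
|--------|-----------------------------------------------------|--------|-----|
| low    | ReLU after the 3×3 conv, last conv2 bottleneck      | 4      | 64  |
| middle | same, last conv3 bottleneck                         | 8      | 128 |
| deep   | same, last conv4 bottleneck                         | 16     | 256 |

Because the deep tap is inside the last conv4 block, that block's final
1×1 expansion (and residual add) feeds nothing and is not built; this is
the sub-graph a functional model with these outputs retains, and the
parameter accounting reflects it.

Preprocessing is pinned: scale to [0, 1], then per-channel
standardization with ImageNet statistics (mean .485/.456/.406, std
.229/.224/.225).

Initialization is seeded He-normal (the configuration seed fixes every
weight); a checkpoint path can restore trained weights. No pretrained
weights are bundled.

### Attention

SimAM assigns each activation the importance E⁻¹ = d/(4·max(v, λ)+0.5)
with d the squared deviation from the channel's spatial mean and
v = Σd/(HW−1); the output is x·σ(E⁻¹). λ (default 10⁻⁷) guards the
division for near-constant channels; it is applied as max(v, λ), exactly
as the reference formulation prints it (not v+λ as some variants use).
A spatially constant channel yields exactly 0.5·x; otherwise outputs lie
strictly between 0.5·|x| and |x| with the sign preserved. Attention is
applied at the taps, before the features fan out to the encoder and both
decoder branches, and adds no parameters. The module is built from
differentiable primitives so the attention weights carry gradients.
Alternative attentions can be plugged in behind the same enum, but only
`none` and `simam` ship.

### Encoder (ASPP)

Five branches on the (attended) deep tap: 1×1 conv; three 3×3 atrous
*separable* convolutions at dilation rates 6/12/18 (depthwise dilated 3×3
→ pointwise 1×1 → BN → ReLU); and image-level average pooling followed by
a 1×1 conv and bilinear broadcast back. All branches produce 256
channels, are concatenated (1280 ch) and projected by a 1×1 conv to 256.

### Decoder

The low tap is reduced 64→48 by a 1×1 conv (+BN+ReLU). The middle-layer
branch — this model's structural addition — reduces the middle tap
128→48 and bilinearly upsamples ×2. Both join the ×4-upsampled encoder
output in a 352-channel concatenation at stride 4, refined by **two**
dense 3×3 convolutions with 256 filters (+BN+ReLU each), then a 1×1
classifier with K filters and bias, and a bilinear ×4 upsample to full
resolution. Because the 1×1 classifier and bilinear resizing are both
linear they commute exactly; the implementation classifies before the
final upsample, which resizes K channels instead of 256.

Ablation switches reproduce the design-study lattice: `attention`
('none'/'simam'; zero parameter difference) and `use_mid_layer` (drops
the 48-channel middle reduction and narrows the first refinement conv;
−116,928 parameters).

### Parameter accounting and its calibration

`count_parameters` sums every weight array exactly; batch-norm moving
statistics (2 per BN channel, 32,832 total) are non-trainable and
reported separately but included in the total, as framework summaries
count them. Bias conventions are pinned: backbone convolutions carry
biases (Keras ResNet50 layout); head convolutions followed by BN are
bias-free except the ASPP pooling-branch conv; the classifier carries a
bias.

Two printed figures from the reference implementation calibrate the
under-specified widths: the companion DeepLabv3+(ResNet50) baseline count
of 27.91 M is reproduced to the printed precision (27,907,963) only by a
head with separable ASPP branches and two dense 3×3 decoder refinement
convolutions — fixing those two choices — and the full model's published
10,406,762 then brackets our reconstruction within one part in 10⁴
(10,405,899 under these conventions; +1,025/−863 under the nearest bias
variants). An exhaustive search over bias placement, BN placement,
reduction widths 16–256, refinement variants and backbone prunings found
no conventional architecture matching the published figure exactly, so
the residual 863-parameter gap is attributed to an unrecoverable detail
of the reference graph; the package reports its own exact count.

FLOP estimates use a stated multiply-accumulate convention (1 MAC =
1 FLOP; normalization, activations, pooling and resizing ignored) and
are for relative comparison only.

## Numerical and engineering choices

* **Autodiff engine.** All layers run on a small reverse-mode engine over
  NumPy (NHWC layout, float32 by default, float64 respected for tests).
  Convolutions are im2col + one GEMM with channels innermost; the fused
  conv→BN→ReLU op normalizes in place on the GEMM output and recovers
  x̂ = (z − β)/γ in the backward pass (γ floored at 1e-20), which the
  finite-difference suite verifies against the unfused composition.
  A bias feeding a train-mode BN receives an exactly zero gradient (it is
  absorbed by the mean subtraction) — a property of the architecture, not
  a defect; gradient-flow tests therefore run with inference-mode BN.
* **Bilinear resizing** uses the half-pixel-center convention
  (align_corners=false): output o reads source (o+0.5)·n_in/n_out − 0.5,
  clipped. Forward is a separable gather-lerp; backward applies the exact
  transposed interpolation matrices.
* **Batch norm**: momentum 0.9, ε = 10⁻³, moving statistics updated in
  train mode only.
* **Max-pool** tie-breaks route the gradient to the first maximal window
  position (scan order), matching argmax semantics.
* **Argmax→mask** tie-breaks choose the lowest class index.

## Training

The full-run recipe follows the study configuration: Adam, initial
learning rate 1e-4, categorical cross-entropy over all pixels (background
is a scored class), reduce-on-plateau on validation loss with patience
25 and factor 0.8 (floor 1e-7), 250 epochs, batch 4, 512×512 inputs. Runs
are deterministic given (config, seed): weight init, shuffling and the
optimizer all derive from the seed, and history files reproduce bitwise.
No data augmentation is applied (hooks could be added, but default off).

The overfit-sanity driver (`train_steps`) trains a fixed number of steps
on an in-memory set; the desk-scale experiment used throughout is 8
synthetic 128×128 scenes, 300 steps, Adam at 1e-3, batch 4 (batch 2 was
tried first but its gradient noise underfits rare classes in so few
steps), with the training mIoU computed in one batch-statistics pass over
the full set — the regime the optimizer saw; after only 300 steps the
moving averages still lag the weights, so inference-mode evaluation
understates a model this young. The run reaches mIoU ≈ 0.955.

## Metrics

The confusion matrix accumulates int64 pixel counts (rows = truth,
columns = prediction); accumulation is associative, so streaming over
images equals one pass over their concatenation. mPA implements the
per-class *binary* accuracy mean literally — (TPᵢ+TNᵢ)/total averaged
over classes — which, for K classes, differs from the global fraction of
correctly labelled pixels (`global_accuracy`, also exposed; with large
true-negative counts the literal form sits close to 1 even for mediocre
segmentations, which is why both are reported). mIoU averages
TPᵢ/(TPᵢ+FPᵢ+FNᵢ) over classes, excluding classes absent from both
prediction and truth rather than scoring them zero. Background is
included in the means by default; `ignore_background=True` restricts to
food classes (the per-class table of a trained model is conventionally
reported that way).

## Annotations, rasterization and statistics

VIA-2 project-export JSON is parsed into per-image polygon sets
(non-polygon regions skipped with a surfaced count; unknown labels
reported; vertices clipped to image bounds). Rasterization paints regions
in file order (painter's order: later regions overwrite earlier) using an
even-odd crossing-number fill sampled at pixel centers ((c+0.5, r+0.5))
with half-open edge spans — deterministic, and validated against an
independent ray-casting oracle and shapely point-in-polygon tests.
Regions covering no pixel center are counted as degenerate, never
silently dropped. Masks round-trip losslessly through indexed PNG with a
documented palette.

Dataset statistics report object occurrences per class, the distribution
of distinct non-background classes per image (one/two/three/four — the
corpus-summary layout), and object-size bands: relative size r =
object pixels / image pixels with r < 5% small, 5% ≤ r ≤ 20% medium,
r > 20% large. The default size measure is mask pixel count (what the
band figure describes); a bounding-box mode is available behind a flag.

## Synthetic data

The generator emulates the *structure* of a plated-food segmentation
corpus, not its appearance: 10 food classes + background; class count per
image drawn from the training-split distribution (76.65 / 22.09 / 1.16 /
0.10 % for one–four classes); object-size bands targeted at 16.09 /
43.95 / 39.96 % small/medium/large; smooth blob outlines (radial
harmonic perturbations of an ellipse, so no degenerate slivers); per-class
distinctive mean colors (pairwise RGB distance > 30) with optional
Gaussian texture noise (σ = 12); pixel-exact masks, matching VIA-2 JSON
and a bookkeeping record of every region's class, painted pixel count and
band. Everything derives from one integer seed, bitwise reproducibly.

Placement is strictly non-overlapping so bookkeeping stays exact under
painter's order. The object count and the band vector of an image are
drawn once and held fixed across placement retries (retrying only
positions), keeping both distributions unbiased — verified against the
target multinomial over 4,000 generated images. Band vectors with more
than two large objects are re-drawn (three objects above 20% of the image
cannot pack without overlap — as on a physical plate); this rejects
under 0.1% of draws. Infeasible configurations (e.g. forcing four large
objects) raise a generation error after a bounded retry budget.

What passing tests on this corpus do **not** show: robustness to real
photographs' intra-class variation, inter-class visual similarity,
lighting, occlusion or annotation noise. The synthetic classes are
color-separable by construction; results on them are sanity checks of
the pipeline's correctness, not of real-world segmentation quality.
Reproducing the published real-data accuracy requires the public corpus
and GPU-scale training with the full-run recipe above.

## Problem sizes used in the shipped experiments

Chosen as desk-scale defaults: gradient checks on ≤ 2×8×8×3 float64
problems; shape/equivalence tests at 32–256 px; the overfit experiment at
8 images × 128²; statistics recovery on 200 generated images at 128²
(seven simultaneous category checks use Bonferroni-adjusted exact
binomial bounds for joint 95% coverage); the parameter account at the
full 512² configuration.
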