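# Methods

## The model

`axunet` implements a U-shaped binary-segmentation network for lesion
images whose encoder runs two feature extractors *in parallel* and fuses
them at every scale:

1. **Residual stem.** The first two stages of a five-stage bottleneck
   residual backbone (7×7 stride-2 conv → max-pool → stage 1 → stage 2)
   aggregate low-level texture at H/2, H/4 and H/8; every scale is kept for
   decoder skip connections. Stage widths scale with a single base width
   `w` (64 at full scale) as `w, 4w, 8w, 16w, 32w`.

2. **Parallel encoder units** (two by default). Each unit pairs
   - a *masked axial transformer branch*: the unit input is average-pooled
     2×2 into a token grid, projected to the unit width, and passed through
     pre-norm transformer blocks whose attention is the distance-masked
     axial form described below; and
   - a *convolutional branch*: one stride-2 bottleneck residual stage
     (stages 3 and 4 of the backbone), which models short-range detail.
   The two outputs land on the same grid and are merged by global–local
   fusion (GLF).

3. **Bottleneck.** A 1×1 reduction followed by standard dense-attention
   transformer blocks on the H/32 grid.

4. **Decoder.** Per stage: bilinear ×2 upsampling, concatenation of the
   matching skip, two 3×3 conv + batch-norm + ReLU. A 1×1 head produces
   segmentation logits at input resolution; a second 1×1 head produces
   auxiliary edge logits.

### Masked axial attention

Queries and keys are computed from axial profiles: the C×H×W token grid is
mean-pooled over width to give per-row vectors `f_H` (and over height for
`f_W`), shared linear maps produce Q and K on both axes, and per head the
axial correlations `corr_H = Q(f_H)·K(f_H)ᵀ` (H×H) and `corr_W` (W×W) are
formed. This makes the correlation stage O((H²+W²)·C) instead of the dense
O((HW)²·C) — on a 32×32 grid the measured multiply–accumulate count is
~0.2 % of the dense figure.

Each correlation matrix is multiplied elementwise by a **distance weight
mask** with curvature `k` (default 0.5) and cutoff `a` (default ⌈n/2⌉ for an
axis of length n):

    mask[i,j] = 1                    i = j
              = k·|i−j|² − k·a² + 1  0 < |i−j| < a
              = 1                    |i−j| ≥ a

The parabola dips below 1 (and below 0 for usual k, a) near the diagonal,
suppressing short-range pairs whose structure the convolutional branch
already models, and returns to 1 at the cutoff. Note the definition is
discontinuous at the diagonal: the diagonal itself stays at 1 while the
immediately adjacent entries take the most negative values. We implement
the rule exactly as defined; a `clamp_mask` switch floors the mask at 0 for
users who prefer to avoid sign flips on negative correlation entries
(off by default).

The two masked axial matrices are recombined into joint token-pair logits —
`logit[(i,j),(i′,j′)] = (mask∘corr_H)[i,i′] · (mask∘corr_W)[j,j′]`, a
separable (Kronecker) product over row-major-flattened tokens — then scaled
by 1/√head_dim, softmaxed over keys, and applied to V. V is a linear map
of the **full, unpooled** token sequence: pooling V would collapse the
output to rank one per axis. Softmax and scaling follow the ordinary
multi-head-attention convention; the joint (HW)×(HW) weight matrix is
materialized only for the softmax/V product (its softmax is not separable),
which is acceptable because the grids at the encoder's depth are small.

Blocks are pre-norm (`z′ = MSA(LN(z)) + z; z″ = MLP(LN(z′)) + z′`) with a
GELU MLP. No learned positional embedding is added: spatial order enters
through the parallel convolutional branch and the distance mask.

### Global–local fusion

The global (transformer) stream produces two sigmoid gates in the
convolutional-block-attention style — a spatial map from channel-axis
mean/max pooling + 7×7 conv, and per-channel gates from global average
pooling + bottleneck MLP — that multiply the local (convolutional) stream
only. The fused output is

    f_out = conv(cat(conv(f_global), f_local · A_s · A_c))

i.e. the global stream is compressed by a 3×3 conv+BN+ReLU, concatenated
with the gated local stream, and a final 3×3 conv+BN+ReLU sets the unit
width. Note the pooling axes: a *spatial* map must pool over channels and
*channel* gates must pool over space; prose descriptions of such modules
sometimes swap the names, and we follow the convention that makes the
shapes work. The gates deliberately do not re-enter the global stream.

### Loss

    L_total = α·L_BCE(G,P) + β·L_Dice(G,P) + γ·L_Ohem(G_edge, P_edge)

with α, β, γ = 0.5, 0.3, 0.2. Dice is the soft form
`1 − (2Σyp + ε)/(Σy + Σp + ε)` with ε = 1. (A variant without the factor 2
in the numerator — under which a perfect prediction scores 0.5 rather
than 0 — is available as `dice_as_printed` for strict comparisons; the
factor-2 form is the default because the evaluation metric itself carries
the 2 and a loss should attain 0 at its optimum.) Losses are pixel-mean
reduced by default so learning rates are independent of image size; sum
reduction is a flag.

Edge ground truth is derived from the mask by Canny detection (mask scaled
to 0–255; hysteresis thresholds 10/100, a deliberately wide range so the
whole contour survives; smoothing σ = 1.5, chosen so the contour of a
filled shape stays one pixel wide — its pixel count tracks the true
perimeter) and dilated by 1 px so the supervision band is not a hairline.
Because edge pixels are a tiny minority, the edge term keeps only the
hardest pixels: per image, per-pixel BCE is ranked and the top
`max(min_kept, ⌈keep_fraction·n⌉)` pixels (defaults 256 / 0.25) are
averaged; ties at the cutoff break by pixel index, so the loss is
deterministic. Selection is per image, not per batch, so one hard image
cannot monopolize the kept set.

The auxiliary edge prediction comes from a 1×1 head on the final decoder
feature. Where the edge probability should come from is genuinely open; an
alternative that derives it from the spatial-gradient magnitude of the
segmentation probability is provided (`edge_source="gradient"`).

### Metrics

Confusion-matrix scores per image — Dice = 2TP/(2TP+FP+FN),
IoU = TP/(TP+FP+FN), precision, recall — with mDice/mIoU as per-image
means (micro-averaging over pooled counts is a flag). Degenerate images:
empty ground truth with an empty prediction scores 1 everywhere; empty
ground truth with false positives scores 0 on dice/IoU/precision and 1 on
recall. The identity dice = 2·iou/(1+iou) holds for every non-degenerate
table and is exercised in tests.

## Training recipe

SGD, initial learning rate 0.01, momentum 0.9, weight decay 1e-4; cosine
annealing with warm restarts (first cycle 10 epochs, period doubling —
the cycle structure is configurable since only the schedule family is
fixed); batch size 4. Datasets split 8:1:1 into train/validation/test;
the checkpoint with the best validation mDice is retained. Augmentation
per step: random rotation, horizontal/vertical flips, random
crop-and-resize, random elastic deformation (applied identically to
image, mask and edge, nearest-neighbour for label maps), then exactly one
of cutout / coarse dropout / grid distortion / grid dropout applied to the
image only — occluding the label would corrupt supervision.

All randomness flows from one integer seed (parameter initialization,
shuffling, augmentation), and the compute stack is deterministic, so a
run's loss trace reproduces exactly.

## Synthetic data

The generator emulates low-contrast lesion photography: 1–3 star-convex
blobs (ellipses modulated by low-order harmonics), filled with a
tissue-toned intensity offset of 0.35, boundary-blurred with σ = 2 px,
over a background carrying smooth low-frequency texture and per-pixel
noise (σ = 0.06). Masks record blob interiors before blurring; edges are
Canny-derived. Everything is deterministic from (seed, index).

What it does *not* emulate: specular highlights, vignetting, instrument
occlusion, perspective distortion of a tube-shaped lumen, multi-organ
context, or annotation noise. Passing the synthetic acceptance runs shows
the architecture and training loop can learn fuzzy low-contrast boundaries
end to end; it does not certify clinical benchmark performance.

## Numerical and engineering choices

- The package runs on its own reverse-mode autodiff engine over NumPy
  (float32 activations; float64 honoured for gradient-checking). Conv and
  pooling are implemented by kernel-offset accumulation; matmul and conv
  feed a multiply–accumulate counter used for the complexity measurement.
- Probabilities are clipped to [1e-7, 1−1e-7] inside BCE; softmax
  subtracts the row max; batch-norm ε = 1e-5, layer-norm ε = 1e-5.
- Masks resize with nearest-neighbour, images bilinearly.
- Desk-scale problem sizes: the test configuration is 64×64 input, base
  width 8, unit widths (32, 64), one transformer block per unit and in the
  bottleneck, 2 heads. The overfit experiment uses 8 samples × 200
  optimizer steps; the generalization experiment 200 training samples,
  15 epochs, 50 held-out samples. The full-scale defaults (512×512, base
  width 64, depths 2/4, 8 heads) are exercised for shape contracts only.

## Limitations

- Binary segmentation only; multi-class would need a softmax head and
  one-hot losses.
- The joint attention weight matrix is materialized at (HW)² per head, so
  the axial saving applies to the Q·K stage, not peak memory.
- CPU-only; no mixed precision or device parallelism.
- Pretrained backbone weights are supported via checkpoints but no
  published weight conversion is bundled.
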