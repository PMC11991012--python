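# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## Episodic problem setting

The segmenter is trained and evaluated on 1-way K-shot episodes: K support
image–mask pairs and one or more query images of a single organ class,
with support and query drawn from the same class-conditional distribution.
Classes used for evaluation are held out of training ("setting 2"), or
allowed to appear unlabeled in training backgrounds ("setting 1"). The
default experiments are 1-way 1-shot.

## Network

**Encoder.** A single weight-shared encoder serves both branches; weight
sharing is structural (one module object), so support/query consistency is
guaranteed by construction. The default backbone is a three-block strided
CNN (3×3 convolutions, strides 2/2/2, overall stride 8, 64 output
channels), sized for 64×64 desk-scale slices. The final convolution has no
activation so features take both signs and cosine similarity spans its
full range; with all-nonnegative ReLU features, cosine scores crowd near
+1 and the anomaly-score map loses discrimination. Heavier backbones
(e.g. a pretrained residual network tapped at 1/8 resolution) can be
registered behind the same `encode` contract; no test requires one.

**Prototype primitives.** Masked average pooling, the negative scaled
cosine anomaly score (`α = 20`), and the shifted-sigmoid soft threshold
(`k = 0.5`) are the shared primitives. The cosine denominator clamps
feature norms at `1e−8` so dead activations keep a defined gradient; a
prototype with norm below that raises `DegeneratePrototype` instead of
silently producing noise.

**Dual-filter cross attention.** The prior query mask is produced by
thresholding the query's anomaly scores against the prior support
prototype at `T_a = −10`. Both branches are fused with the tiled prior
prototype and their mask through one shared 1×1 convolution (input
`2C+1` channels). Cross attention runs over all pixels of the feature grid
as tokens, single-head, with the attention query projected from the branch
being enhanced and keys/values from the other branch — the output must
stay spatially aligned with the enhanced branch. Two filters remove
background influence: the Hadamard mask gate on each branch, and the
adaptive score filter that discards entries not exceeding
`V_filter = (max + mean)/2` (computed globally over the score matrix).
Rows left without a surviving entry fall back to their maximal allowed
entries, so the softmax is always defined; key tokens whose mask weight is
exactly zero are excluded outright. Background restore is the mask-gated
composition `F_enh = M ⊙ attended + (1−M) ⊙ F_fused`.

**Onion pooling.** Erosion pooling inverts the mask, 2×2 max-pools the
background with stride 1 (top-left anchor, out-of-bounds treated as
background), and inverts back — morphological erosion of the foreground by
a 2×2 structuring element, size-preserving so every onion layer can be
pooled against the same feature grid. The un-eroded support mask is layer
1 by default (`include_base_layer`), guaranteeing at least one prototype
even for organs that vanish after one erosion; erosion stops before an
empty layer or at `N_max = 4` layers. Erosion operates at feature
resolution, where the pooling happens. The per-layer prototypes are mixed
by a single-head self-attention without positional encoding, so mixing is
permutation-equivariant.

**Refinement and aggregation.** The refinement stage is a registry of
strategies; the default pools a coarse query prototype under the prior
query mask and adds a learned value-projection residual with weight
`γ = 0.5` to every support prototype. With a single key token the
attention weight is identically one, so query/key projections would be
dead weights and are omitted. When the prior mask is nearly empty
(weight ≤ 1e−3) the stage passes prototypes through unchanged — there is
no usable coarse prototype, and the pooled gradient, which scales like
`1/(ΣM)²`, would explode. Global aggregation is the elementwise mean,
computed with exactly-rounded summation so it is bit-identical under
permutation of the prototype set.

**Threshold perception and segmentor.** The raw and enhanced query
features are concatenated and passed through one shared 3×3 convolution;
a max-pool branch keeps salient structure and an avg-pool branch the
overall field. The concatenated branches are downsampled by 3×3-conv +
ReLU + 2×2-max-pool blocks until the grid is at most 4×4 (the repetition
count adapts to the feature resolution, keeping the fully-connected input
fixed), then flattened into a single scalar threshold `T_p` per episode.
The FC weights initialize small with bias at −10, so an untrained head
reproduces the fixed prior-threshold baseline. The segmentor thresholds
the query's anomaly-score map against the aggregated prototype at `T_p`.

**Resolution handling.** Hard masks are downsampled to the feature grid by
nearest neighbor. Soft masks used as pooling weights stay at feature
resolution. The image-resolution predicted and prior masks are produced by
*bilinearly upsampling the anomaly-score field* and applying the shifted
sigmoid at image resolution, rather than upsampling the already-
thresholded soft mask: the score is the natural continuous quantity, and
interpolating after the saturating sigmoid smears the organ boundary. On
the fixed overfit episode the best achievable binarized Dice through an
8×8 mask is 90.7% when probabilities are interpolated but 96.9% when the
score field is; the training loss is also strictly lower in score space.

## Objective

`L_total = L_s + L_q + L_par + L_qsr`, all nonnegative mean binary
cross-entropies with predictions clipped to `[1e−7, 1−1e−7]`:

* `L_s`: predicted query mask vs. ground truth, at image resolution.
* `L_q`: the prior-mask branch vs. ground truth, at image resolution —
  supervising the prior pathway directly. (The alternative reading, a
  second pass with the unrefined prototypes, is exposed in config.)
* `L_par`: the soft predicted query mask pools a query prototype that must
  re-segment the support features (role swap), scored against the support
  mask at feature resolution.
* `L_qsr`: the same self-reference construction on the query itself,
  scored against the query mask at feature resolution and scaled by
  `β = 0.02·(epoch+1)` — the feedback term strengthens as predictions
  become trustworthy.

Soft predicted masks are used directly as pooling weights (no
binarization) to keep every term differentiable. When a predicted mask is
too empty to pool from — routine in the first iterations — the role-swap
terms contribute zero and a warning is logged.

## Training

SGD with momentum 0.9, learning rate 0.001 decaying by 0.98 per epoch
(5 000 iterations per epoch, 15 000 total by default), batch size one
episode. The optimizer identity is a package choice — the prototype-
network lineage this model belongs to conventionally trains with
SGD+momentum — and is exposed in config. Gradients are clipped to global
norm 5: the masked-pooling gradient scales like `1/(ΣM)²` and can spike
when a soft pooling mask is transiently near-empty. All weights initialize
from explicit seeds; two runs with the same config and seeds are
bit-identical, and checkpoints carry model weights, optimizer momentum and
the iteration count so a resumed run matches an uninterrupted one.

The smoke experiments in the test suite and acceptance script run at desk
scale: 200 iterations (overfit on one fixed 64×64 episode) and 500
iterations (generalization to a held-out class, 20 evaluation episodes),
with learning rate 0.05 — a standard short-run rate for SGD+momentum at
this model size, chosen once as part of the experiment definitions.

## Synthetic episodes

Each class is a distribution over smooth organ-like blobs: an ellipse with
low-frequency radial boundary perturbation, a characteristic foreground
area fraction (5–18% of the image, class-dependent), an intensity offset
of 0.35–0.6 above a smoothly textured background (~0.25), and additive
Gaussian noise (σ = 0.05) — chosen to resemble the geometry and contrast
of abdominal organs in normalized 2D slices at desk scale. Support and
query are independent draws from the same class distribution. Distractor
organs from other classes can be painted into the background without
entering the label mask; the setting-2 stream guarantees the held-out
class appears nowhere in training images.

What the generator does **not** emulate: imaging physics (bias fields,
partial-volume effects, modality-specific noise), 3D anatomical
continuity between slices, inter-subject anatomical variability beyond
shape statistics, and multi-organ context. Passing the synthetic
experiments therefore demonstrates that the pipeline is implemented
coherently and can learn and transfer shape/contrast statistics — not
that it reaches any particular accuracy on real MRI/CT data.

## Numerical choices and degenerate inputs

* Cosine norms clamped at `1e−8`; mask-weight emptiness threshold `1e−5`;
  probability clipping `1e−7` before logarithms.
* Masked softmax shifts each row by its own surviving maximum, so the
  normalizer never underflows however far apart the rows' score ranges
  are; discarded entries are gated out before the exponential so they can
  neither overflow nor receive gradient.
* Max reductions route gradient to the first arg-max on ties.
* Dice of two empty masks is defined as 100% (both agree there is no
  organ); Dice is reported on the percentage scale.
* Soft masks are binarized at 0.5 wherever a hard decision is needed.
* An all-background support mask raises `EmptyMask` at the first pooling;
  the generator never produces one.

## Known limitations

* The prototype-refinement default is deliberately minimal; it fixes only
  the interface (prototype set + query features in, same-sized set out)
  and is not a reimplementation of any published refinement transformer.
* The fully-connected threshold head is built for a fixed feature
  geometry; changing the encoder stride or input size requires a new head
  (handled automatically when the model is constructed from config).
* One attention head everywhere; no positional information. At 8×8
  feature grids this is adequate, but larger grids may warrant more.
* Training is CPU-bound and single-episode; the default 15 000-iteration
  schedule is practical at 64×64 but slow at 256×256.
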