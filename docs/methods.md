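# Methods

This note records the modelling choices behind `lgfusion`, the defaults
and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical conventions used throughout.

## Model

### Backbone contract

The embedding model consumes a four-level feature pyramid at strides
4/8/16/32 from a frozen, stage-wise convolutional backbone.  The adapter
is variant-agnostic: any network producing four maps with non-decreasing
channel counts satisfies the contract.  The default configuration
declares tiny-class stage widths (96, 192, 384, 768); input
normalization (per-channel mean/std) is part of the backbone
configuration, not of the pipeline.  Inputs must be square with side
divisible by 32 so that all strides divide exactly; the default side is
224.

Freezing is the training regime, not an optimization detail: only the
neck and head (and the loss head's sub-center bank) receive gradients.
An `unfreeze_backbone` flag exists for experimentation and is off by
default.

### Aggregator units

Both units gate the input elementwise, `a·X + (1−a)·X⊙σ(op(X))`, with a
single trainable scalar `a` per unit initialized at 0.5 and left
unconstrained during optimization.  The gate is per element because
every stage of the inner operator is shape-preserving.

The global operator is `PW(GRN(δ(PW(DW(X)))))`: a depthwise 3×3
convolution for spatial context, a point-wise squeeze C → C/r, the
activation δ, Global Response Normalization on the reduced channels, and
a point-wise expansion C/r → C.  The local operator omits the spatial
and normalization stages: `PW(δ(PW(X)))`.  Choices:

- **r = 2** (from the conventional {2, 4}).  r = 2 is the default
  because it brings the full-size neck+head parameter count closest to
  the reported total (see "Parameter count" below); r = 4 roughly halves
  the aggregator cost at some capacity loss.
- **δ = GELU**, matching the convnext-style backbone family; relu,
  sigmoid and identity are configurable alternatives.
- **GRN** follows the convnext-v2-style definition: per-channel spatial
  L2 norms, divisively normalized by their cross-channel mean (epsilon
  1e-6 in the divisor), scaled/shifted by trainable per-channel γ/β
  (initialized at zero, so a fresh layer is the identity) with an
  identity residual.  A 1e-24 floor inside the square root keeps the
  all-zero input differentiable.
- Convolutions are bias-carrying, stride 1, with padding that preserves
  spatial size.

### Fusion neck

Each layer evaluates six fusion nodes in a fixed order — top-down
P3₁ → P2₁ → P1₂, then bottom-up P2₂ → P3₂ → P4₂ — so the two
intermediate nodes are reused by later nodes; this ordering is what
makes a layer bidirectional.  Node inputs are gated by *per-edge,
per-layer* aggregator units (no sharing), globally-gated on lateral and
downsampled edges or locally-gated on upsampled and skip edges according
to the node definitions in `neck.py`.

Fast Normalized Fusion weights are initialized at 1.0 and rectified at
use time (`relu`), with ε = 1e-4 in the denominator; the effective
coefficients are therefore non-negative and sum to Σrelu(w)/(Σrelu(w)+ε)
< 1.  Upsampling is nearest-neighbour ×2 and downsampling 2×2 max
pooling, both parameter-free; the resize direction is dictated by
spatial compatibility of each node's operands (P1 is the
highest-resolution level).  A single per-level 1×1 projection (with
bias) maps backbone channels to the inner width Cin before the first
layer; later layers run at Cin throughout.  Defaults: 3 layers,
Cin = 512.

### GeM head and descriptor

Each terminal node owns a mini-head: GeM pooling with its own trainable
exponent (initialized at 4.6, clamp floor 1e-6 on activations), a fully
connected Cin → Cin layer, L2 normalization, and a second Cin → Cin
layer; no activation between the FCs.  GeM interpolates between average
(p = 1) and max pooling (p → ∞); for a map with N spatial positions and
a unique maximum the pooled value is max·(1/N)^(1/p)·(1 + o(1)), so the
approach to the max is governed by N — at p = 100 a two-position map is
within 0.7% of the max while a 6×6 map is ~3.5% below it.  This rate is
asserted exactly in the tests.

The four mini-head outputs are concatenated in level order and the
stacked vector is L2-normalized (configurable, on by default).  The
literal head composition normalizes *between* the FCs and would leave
the final descriptor unnormalized; the final normalization is applied
because the angular-margin loss consumes unit vectors and because on
unit vectors Euclidean ranking coincides with cosine ranking, which
makes the Euclidean retrieval index consistent with the training
objective.

### Loss

Sub-center ArcFace: each class owns K = 3 sub-centers (the conventional
default; configurable), class similarity is the max cosine over the
class's sub-centers, and the target angle is enlarged by m before
scaling by s = 64 and applying softmax cross-entropy.  **The margin is
stored in degrees** (default 17.2° ≈ 0.300 rad); a radian reading of the
same number would exceed the valid margin range, so degrees is the only
consistent interpretation.  Numerical safety: cosines are clipped to
±(1 − 1e-7) before the angle addition, computed via
cos(θ+m) = cosθ·cos m − sinθ·sin m with sinθ = √(1−cos²θ); the margin is
applied unconditionally (no easy-margin variant).  Embeddings must
arrive unit-norm (deviation > 1e-3 is a contract error); the bank is
re-normalized at every use.

### Training

AdamW (β = 0.9/0.999, decoupled weight decay 1e-2) with per-step cosine
annealing from 5e-3 at step 0 to 8e-5 at the final step of each stage.
Defaults: batch 64, 60 epochs for the first stage and 300 for later
stages, images resized to 224.  Staged transfer ("strategy A/B/C")
trains the same neck+head sequentially on one, two or three datasets;
the sub-center bank is re-initialized per stage because class sets
differ across datasets, while the embedding trunk carries over.  The
stage datasets are read as sequential fine-tuning; a pooled mode that
merges stages (with offset class labels) is available behind
`train.pooled_stages`.  Augmentation defaults to flips, 90° rotations
and mild colour jitter and is disabled wherever determinism is asserted.

Checkpoints are single `.npz` archives holding every parameter plus a
JSON header (config, stage provenance, format version); a reload
reproduces embeddings bit-identically.

## Retrieval and metrics

The index contract is exact brute-force Euclidean ranking with ties
broken by database order; the scikit-learn backend is constrained to
reproduce that ranking and is cross-checked against a double-loop oracle
in the tests.  The evaluation protocol defaults to leave-one-out top-1
within the query set; a depth flag generalizes it, in which case each
query contributes its hit fraction |top-d ∩ Γ_s|/d (this reduces to the
standard definition at d = 1 — the scan metrics are only defined for
top-1 in their source formulation, so the generalization is this
package's own convention).  When all scans hold equally many patches,
eta_p = eta_w identically.

## Parameter count

With the defaults (3 layers, Cin = 512, r = 2, laterals 96/192/384/768,
2048-d descriptor) the trainable neck+head count is exactly
**13,984,344**: laterals 739,328; per layer 6 global units × 268,545 +
8 local units × 262,913 + 14 fusion weights = 3,714,588; head
4 × 525,313.  This is ~3.6% below the reported total of 1.45×10⁷ for
this architecture class; no choice of real backbone lateral widths
closes the gap under the stated layer composition (the lateral channel
sum would have to lie in 2349..2544, between the tiny and base
variants), and the expansion reading of the squeeze weights overshoots
several-fold.  The count is therefore reported as computed; the
corresponding acceptance check is left failing rather than loosened.

## Synthetic fixtures: what they show

The fixture generator emits small procedural texture images — oriented
stripes, checkerboards, blob fields, rings, noise fields, gradients —
in class-specific base colours (pairwise colour gaps > 3× the jitter
scale) with within-class jitter in frequency, phase and amplitude, all
reproducible from a seed.  They emulate only the *statistical* role of
training data: separable classes grouped into scans.  They do not
emulate H&E stain physics, nuclei morphology, scanner variation, or the
hard intra-class/inter-class structure of real histology; passing the
desk-scale tests therefore demonstrates that the pipeline optimizes,
embeds and retrieves correctly, not that the model reaches any
particular accuracy on real WSI archives.  Because the fixture classes
are linearly separable by design, held-out Recall@1 near 1.0 is the
expected outcome, and the staged-transfer comparison is asserted as an
ordering (staged ≥ single-stage), not as specific values.

Desk-scale study conditions, fixed in `study.py`: reduced model (fixture
backbone 8/16/32/64, one fusion layer, Cin = 64, 256-d descriptor),
8 classes × 16 images at 64 px with a 12/4 split and 300 steps at batch
16 for the learnability protocol; three domains (6/7/8 classes × 12) at
120 steps per stage for the transfer protocol; augmentation off.

## Degenerate inputs and errors

Non-square or non-divisible-by-32 images, channel mismatches, non-2×
resize ratios, shape-mismatched fusion inputs, empty manifests,
duplicate ids, out-of-range labels and non-positive GeM exponents all
raise typed errors naming the offending quantity.  Non-finite training
loss aborts with a diagnostic rather than continuing.  `query_topk` with
k larger than the index truncates with a warning.

## Known limitations

- Training runs on a numpy autodiff engine on one CPU in float64; it is
  intended for desk-scale experiments and correctness work, not for
  full-dataset training (no GPU, no mixed precision, no data pipeline
  parallelism).
- Checkpoints can reconstruct fixture-variant backbones from their seed;
  external backbones must be re-supplied by the caller at load time.
- Approximate nearest-neighbour indexes are out of scope; the index is
  exact by contract.
- Attribution visualizations (class-activation maps) and 2-D embedding
  projections are not part of the package.
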