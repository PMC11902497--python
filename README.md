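# lgfusion

Local–global feature-fusion embeddings for content-based histopathology
patch retrieval.

## The problem

Content-based image retrieval (CBIR) supports pathologists by finding
visually similar patches across whole-slide image (WSI) archives.  The
usual embedding — the last layer of a pretrained CNN — sees the patch at
a single coarse scale and discards the spatially detailed features of
earlier stages.  `lgfusion` builds patch descriptors that fuse all four
backbone scales instead, so that fine texture (nuclei, stroma) and
coarse semantics (tissue architecture) both reach the embedding.

## The model

Three components, of which only the last two are trained:

1. **Backbone adapter** — any stage-wise convolutional network exposing
   four lateral feature maps P1..P4 at strides 4/8/16/32.  The backbone
   is frozen; a deterministic seeded *fixture backbone* is bundled so the
   whole pipeline runs and tests without pretrained downloads.
2. **Fusion neck** — stacked bidirectional fusion layers.  Each layer
   combines the levels through six fusion nodes with *Fast Normalized
   Fusion* weights, `sum_j relu(w_j) I_j / (sum_j relu(w_j) + eps)`.
   Every input edge is gated by a channel-attention aggregator unit:

   - global unit: `GA(X) = a·X + (1−a)·X⊙σ(PW(GRN(δ(PW(DW(X))))))`
   - local unit:  `LA(X) = a·X + (1−a)·X⊙σ(PW(δ(PW(X))))`

   with a depthwise 3×3 convolution (DW), squeeze/expand point-wise
   convolutions (PW, reduction factor r), Global Response Normalization
   (GRN) and a trainable blend scalar `a` per unit.
3. **GeM head** — per level, generalized-mean pooling with trainable
   exponent (`p = 4.6`), `FC → L2 → FC`, then the four Cin-length vectors
   are stacked and L2-normalized into the final descriptor of length
   4·Cin (2048 at the default Cin = 512).

Training uses the **Sub-center ArcFace** loss (margin m = 17.2°, scale
s = 64, K = 3 sub-centers per class) with AdamW and a cosine-annealed
learning rate (5·10⁻³ → 8·10⁻⁵), optionally over a sequence of dataset
stages ("staged transfer": generic domain → intermediate domain → target
domain).  Retrieval is exact Euclidean nearest-neighbour search; on
unit-norm descriptors this equals cosine ranking.  Evaluation reports
Recall@K and the scan-level accuracies

    eta_p   = sum_s |R ∩ Γ_s| / n_tot        (patch-to-scan)
    eta_w   = (1/|S|) sum_s |R ∩ Γ_s|/n_Γs   (whole-scan)
    eta_tot = eta_p · eta_w

where Γ_s is the patch set of scan s.

The network and its gradients run on a small numpy reverse-mode autodiff
engine included in the package (`lgfusion.autodiff`), so there is no
deep-learning-framework dependency.

## Worked example

Generate an 8-class procedural texture fixture set, train the reduced
desk-scale model (fixture backbone, one fusion layer, Cin = 64), embed
and evaluate:

```sh
lgfusion fixtures --out data --classes 8 --per-class 12 --side 64 --seed 0
cat > cfg.yaml <<EOF
backbone: {variant_name: fixture-0, stage_channels: [8, 16, 32, 64]}
neck: {num_layers: 1, inner_channels: 64}
train: {batch_size: 16, image_side: 64, augment: false, seed: 0}
EOF
lgfusion train --config cfg.yaml --strategy A \
    --manifest data/manifest.csv --steps 150 --checkpoint model.npz
lgfusion embed --checkpoint model.npz --manifest data/manifest.csv --out desc.npy
lgfusion evaluate --descriptors desc.npy --ids desc.npy.ids.csv
```

The evaluation prints leave-one-out retrieval metrics in [0, 1]:

```json
{
  "recall_at_1": 1.0,
  "eta_p": 1.0,
  "eta_w": 1.0,
  "eta_tot": 1.0,
  ...
}
```

i.e. after 150 training steps every patch's nearest neighbour comes from
its own class and scan — the fixture classes are separable by design, so
this checks the pipeline end to end rather than posing a hard retrieval
task.  The trainable-parameter count of the full-size configuration
(3 fusion layers, Cin = 512, r = 2, laterals 96/192/384/768):

```sh
$ lgfusion params
13984344
```

## Layout

- `src/lgfusion/autodiff.py` — numpy reverse-mode autodiff (tensors,
  convolutions, pooling, AdamW)
- `backbone.py`, `aggregators.py`, `neck.py`, `head.py` — the model
- `losses.py` — Sub-center ArcFace
- `retrieval.py` — exact index, Recall@K, eta metrics
- `fixtures.py`, `data.py`, `study.py` — procedural fixtures, dataset
  readers, desk-scale protocols
- `training.py`, `config.py`, `cli.py` — staged training, YAML config,
  `lgfusion` console command
- `docs/methods.md` — modelling assumptions, parameter choices, known
  limitations
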