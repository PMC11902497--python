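"""Training pipeline: staged transfer, checkpoints, embedding export.

The transfer scheme trains the neck and head (the backbone stays frozen)
with the sub-center angular-margin loss on a sequence of dataset stages:

* strategy ``A`` — one stage (a generic source domain);
* strategy ``B`` — two stages (source, then an intermediate domain);
* strategy ``C`` — three stages (source, intermediate, target domain).

Each stage starts from the previous stage's weights; the loss head's
sub-center bank is re-initialized per stage because the class sets
differ between datasets.  AdamW with per-step cosine annealing drives
every stage from ``lr_init`` down to ``lr_min``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np

from .autodiff import AdamW, Module, Tensor, cosine_annealed_lr, no_grad
from .backbone import (
    BackboneConfig,
    ConfigurationError,
    FixtureBackbone,
    extract_pyramid,
    make_fixture_backbone,
)
from .config import ModelConfig
from .head import GemHead
from .losses import SubcenterArcFace
from .neck import Neck

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1

__all__ = [
    "EmbeddingModel",
    "build_model",
    "count_trainable_parameters",
    "train_stage",
    "run_strategy",
    "pool_datasets",
    "save_checkpoint",
    "load_checkpoint",
    "embed_dataset",
    "augment_batch",
]


class EmbeddingModel(Module):
    """Backbone + fusion neck + GeM head; maps image batches to descriptors."""

    def __init__(self, backbone, config: ModelConfig, rng: np.random.Generator):
        self.backbone = backbone
        self.config = config
        self.neck = Neck(backbone.config.stage_channels, config.neck, rng)
        self.head = GemHead(config.neck.inner_channels, config.head, rng)

    @property
    def descriptor_dim(self) -> int:
        return self.head.descriptor_dim

    def forward(self, images: np.ndarray) -> Tensor:
        """(N, H, W, 3) images in [0, 1] -> (N, 4*Cin) descriptors."""
        pyr = extract_pyramid(images, self.backbone)
        return self.head(self.neck(pyr))

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Inference-mode embedding, returning a plain array."""
        with no_grad():
            return self.forward(images).data


def build_model(
    config: ModelConfig | None = None,
    backbone=None,
    seed: int = 0,
) -> EmbeddingModel:
    """Construct a model from a config, building the backbone if needed.

    A ``fixture-<seed>`` variant name rebuilds the deterministic tiny
    backbone; any other variant requires an explicit backbone instance
    honouring the pyramid contract.
    """
    config = config if config is not None else ModelConfig()
    if backbone is None:
        name = config.backbone.variant_name
        if name.startswith("fixture-"):
            backbone = make_fixture_backbone(
                int(name.split("-", 1)[1]), config.backbone.stage_channels
            )
        else:
            # weight values are irrelevant for architecture-level uses
            # (parameter counting, shape checks); a seeded fixture-style
            # backbone realises the declared stage widths
            backbone = FixtureBackbone(config.backbone, seed)
    if tuple(backbone.config.stage_channels) != tuple(config.backbone.stage_channels):
        raise ConfigurationError(
            f"backbone channels {backbone.config.stage_channels} disagree with "
            f"config {config.backbone.stage_channels}"
        )
    rng = np.random.default_rng(seed)
    return EmbeddingModel(backbone, config, rng)


def count_trainable_parameters(model: EmbeddingModel, scope: str = "neck_and_head") -> int:
    """Count trainable scalars: lateral projections + neck layers + head.

    The frozen backbone and the loss head's sub-center bank are excluded
    under the default scope.
    """
    if scope == "neck_and_head":
        return model.neck.num_parameters() + model.head.num_parameters()
    if scope == "all":
        return model.num_parameters()
    raise ValueError(f"unknown scope {scope!r}")


def augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flips, 90-degree rotations and mild colour jitter (per image)."""
    out = images.copy()
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, ::-1]
        out[i] = np.rot90(out[i], k=int(rng.integers(0, 4)))
        jitter = 1.0 + 0.05 * rng.standard_normal(3)
        out[i] = np.clip(out[i] * jitter, 0.0, 1.0)
    return out


def _trainable_parameters(model: EmbeddingModel, loss_head: SubcenterArcFace):
    params = list(model.neck.parameters()) + list(model.head.parameters())
    if model.config.train.unfreeze_backbone:
        params += list(model.backbone.parameters())
    return params + list(loss_head.parameters())


def train_stage(
    model: EmbeddingModel,
    dataset,
    stage_index: int = 0,
    steps: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SubcenterArcFace, list[dict]]:
    """Train neck + head (+ fresh loss bank) on one dataset stage.

    ``steps`` overrides the epoch-derived step count (tests use short
    step-capped runs).  Returns the stage's loss head and a per-step
    history of learning rate and loss.  Aborts on non-finite loss.
    """
    cfg = model.config
    tc = cfg.train
    n = dataset.n_images
    if n == 0:
        raise ValueError("empty dataset")
    if rng is None:
        rng = np.random.default_rng(tc.seed + 1000 * stage_index)
    batch = min(tc.batch_size, n)
    if steps is None:
        epochs = tc.epochs_per_stage[min(stage_index, len(tc.epochs_per_stage) - 1)]
        steps = epochs * math.ceil(n / batch)
        if tc.max_steps_per_stage is not None:
            steps = min(steps, tc.max_steps_per_stage)
    loss_head = SubcenterArcFace(dataset.n_classes, model.descriptor_dim, cfg.loss, rng)
    opt = AdamW(
        _trainable_parameters(model, loss_head),
        lr=tc.lr_init,
        weight_decay=tc.weight_decay,
    )
    if model.backbone.config.frozen and not tc.unfreeze_backbone:
        frozen_before = _weights_digest(model.backbone)
    history = []
    labels = np.asarray(dataset.labels)
    for step in range(steps):
        opt.lr = cosine_annealed_lr(step, steps, tc.lr_init, tc.lr_min)
        idx = rng.choice(n, size=batch, replace=False)
        images = dataset.load(idx)
        if tc.augment:
            images = augment_batch(images, rng)
        embeddings = model(images)
        loss = loss_head(embeddings, labels[idx])
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss {value} at step {step} (lr={opt.lr:.2e}); aborting"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "lr": opt.lr, "loss": value})
        logger.debug("stage %d step %d lr %.3e loss %.4f", stage_index, step, opt.lr, value)
    if model.backbone.config.frozen and not tc.unfreeze_backbone:
        assert _weights_digest(model.backbone) == frozen_before, "frozen backbone moved"
    return loss_head, history


def _weights_digest(module: Module) -> bytes:
    import hashlib

    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.digest()


def pool_datasets(datasets):
    """Concatenate array datasets into one, offsetting class labels."""
    import pandas as pd

    from .data import ArrayDataset

    frames, images, offset = [], [], 0
    for ds in datasets:
        frame = ds.manifest.copy()
        frame["class"] = np.asarray(frame["class"]) + offset
        frame["id"] = [f"d{offset}_{i}" for i in frame["id"]]
        offset += ds.n_classes
        frames.append(frame)
        images.append(ds.images)
    return ArrayDataset(np.concatenate(images), pd.concat(frames, ignore_index=True))


def run_strategy(
    strategy: str,
    datasets,
    model: EmbeddingModel,
    steps_per_stage: int | None = None,
    checkpoint_dir: str | Path | None = None,
):
    """Run the staged transfer scheme ``A``/``B``/``C``.

    ``datasets`` supplies one dataset per stage in order; strategy ``A``
    uses the first, ``B`` the first two, ``C`` all three.  In pooled mode
    all selected stages are merged into a single training stage instead.
    Returns (model, provenance log).
    """
    n_stages = {"A": 1, "B": 2, "C": 3}.get(strategy)
    if n_stages is None:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if len(datasets) < n_stages:
        raise ConfigurationError(
            f"strategy {strategy} needs {n_stages} datasets, got {len(datasets)}"
        )
    selected = list(datasets[:n_stages])
    if model.config.train.pooled_stages and n_stages > 1:
        selected = [pool_datasets(selected)]
    provenance = []
    for k, dataset in enumerate(selected):
        _, history = train_stage(model, dataset, stage_index=k, steps=steps_per_stage)
        provenance.append(
            {
                "stage": k,
                "strategy": strategy,
                "n_images": dataset.n_images,
                "n_classes": dataset.n_classes,
                "steps": len(history),
                "final_loss": history[-1]["loss"] if history else None,
            }
        )
        if checkpoint_dir is not None:
            save_checkpoint(
                Path(checkpoint_dir) / f"stage{k}.npz", model, provenance
            )
    return model, provenance


# ---------------------------------------------------------------------------
# checkpointing and embedding export
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    model: EmbeddingModel,
    provenance: list | None = None,
    loss_head: SubcenterArcFace | None = None,
    include_loss: bool = True,
) -> None:
    """Single-file checkpoint: all weights plus config and provenance.

    The loss head is training state only; pass ``include_loss=False`` for
    an inference/export artifact.
    """
    from .config import config_to_dict

    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if loss_head is not None and include_loss:
        arrays.update({f"loss/{k}": v for k, v in loss_head.state_dict().items()})
        arrays["loss/__meta__"] = np.array(
            [loss_head.num_classes, loss_head.embed_dim], dtype=np.int64
        )
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": config_to_dict(model.config),
        "provenance": provenance or [],
    }
    arrays["meta.json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path, backbone=None):
    """Rebuild the model from a checkpoint; bit-identical embeddings.

    Fixture-variant backbones are reconstructed from their seed; other
    variants need the backbone instance passed in (its weights are then
    overwritten from the stored state).
    """
    from .config import config_from_dict

    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(bytes(arrays.pop("meta.json")).decode("utf-8"))
    if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported checkpoint format {meta['format_version']}"
        )
    config = config_from_dict(meta["config"])
    model = build_model(config, backbone)
    model_state = {
        k[len("model/"):]: v for k, v in arrays.items() if k.startswith("model/")
    }
    model.load_state_dict(model_state)
    return model, meta["provenance"]


def embed_dataset(
    model: EmbeddingModel, dataset, batch_size: int = 32
) -> tuple[list, np.ndarray]:
    """Order-preserving batch inference over a whole dataset."""
    chunks = []
    for start in range(0, dataset.n_images, batch_size):
        idx = np.arange(start, min(start + batch_size, dataset.n_images))
        chunks.append(model.embed(dataset.load(idx)))
    return list(dataset.ids), np.concatenate(chunks, axis=0)
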