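"""Desk-scale evaluation protocols.

These reproduce the pipeline's behaviour at CPU-friendly sizes: a reduced
model (deterministic fixture backbone with stage channels 8/16/32/64, one
fusion layer at Cin=64, descriptor length 256) trained on the 8-class
procedural texture fixtures.  Two protocols are defined:

* :func:`learnability_study` — train on a per-class split of one fixture
  set and measure held-out leave-one-out Recall@1 plus the scan-level
  accuracies (scans coincide with classes in the default fixture layout);
* :func:`transfer_study` — mirror the staged-transfer comparison: a
  single-stage run on a source domain alone versus a three-stage run that
  ends on the target domain, both evaluated on the same held-out target
  split.

Problem sizes (128 or 96 images per domain, 300 / 120 optimization steps
at batch 16, 64-pixel images) are the package's desk-scale study
conditions; they are fixed here rather than tuned per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .backbone import BackboneConfig
from .config import ModelConfig, TrainConfig
from .data import ArrayDataset
from .fixtures import FixtureSpec, generate_texture_dataset
from .neck import NeckConfig
from .retrieval import ScanPartition, build_index, evaluate_run, leave_one_out_run
from .training import build_model, embed_dataset, train_stage

__all__ = ["reduced_config", "learnability_study", "transfer_study"]

LEARNABILITY_STEPS = 300
TRANSFER_STEPS_PER_STAGE = 120
DESK_BATCH = 16


def reduced_config(backbone_seed: int, train_seed: int) -> ModelConfig:
    """The reduced desk-scale model: fixture backbone, 1 layer, Cin=64."""
    return ModelConfig(
        backbone=BackboneConfig(
            variant_name=f"fixture-{backbone_seed}", stage_channels=(8, 16, 32, 64)
        ),
        neck=NeckConfig(num_layers=1, inner_channels=64),
        train=TrainConfig(batch_size=DESK_BATCH, seed=train_seed, augment=False),
    )


def _split_per_class(images, manifest, n_train: int):
    rank = manifest.groupby("class").cumcount()
    train_idx = manifest.index[rank < n_train]
    test_idx = manifest.index[rank >= n_train]
    return (
        ArrayDataset(images[train_idx], manifest.loc[train_idx]),
        ArrayDataset(images[test_idx], manifest.loc[test_idx]),
    )


def _held_out_metrics(model, dataset) -> dict:
    ids, matrix = embed_dataset(model, dataset)
    manifest = pd.DataFrame(
        {"id": ids, "class": dataset.labels, "scan": dataset.scans}
    )
    index = build_index(matrix, manifest)
    run = leave_one_out_run(index, k=1)
    gamma: dict = {}
    for pid, scan in index.scan_of.items():
        gamma.setdefault(scan, []).append(pid)
    part = ScanPartition(gamma={s: tuple(v) for s, v in gamma.items()})
    return evaluate_run(run, part, index.class_of)


def learnability_study(seed: int) -> dict:
    """Train the reduced model on the 8-class fixtures; evaluate held out.

    128 images (16 per class), 12/4 train/test split per class, 300 steps.
    Returns the held-out metric report plus the training loss endpoints.
    """
    spec = FixtureSpec(n_classes=8, n_per_class=16, image_side=64, seed=seed)
    images, manifest = generate_texture_dataset(spec)
    train_ds, test_ds = _split_per_class(images, manifest, n_train=12)
    model = build_model(reduced_config(seed, seed), seed=seed)
    _, history = train_stage(model, train_ds, steps=LEARNABILITY_STEPS)
    report = _held_out_metrics(model, test_ds)
    report["initial_loss"] = history[0]["loss"]
    report["final_loss"] = history[-1]["loss"]
    report["n_test"] = test_ds.n_images
    return report


def transfer_study(seed: int) -> dict:
    """Single-stage versus staged transfer, evaluated on the target domain.

    Three synthetic domains are generated from distinct seeds (the first
    two with fewer classes, the target with 8).  The single-stage run
    trains on the source domain only; the staged run trains on all three
    in sequence with the same per-stage step budget, ending on the
    target's training split.  Both use identically seeded model builds.
    """
    domains = [
        FixtureSpec(n_classes=6, n_per_class=12, image_side=64, seed=seed + 11),
        FixtureSpec(n_classes=7, n_per_class=12, image_side=64, seed=seed + 22),
        FixtureSpec(n_classes=8, n_per_class=12, image_side=64, seed=seed + 33),
    ]
    datasets = []
    for spec in domains:
        images, manifest = generate_texture_dataset(spec)
        datasets.append((images, manifest))
    target_images, target_manifest = datasets[2]
    target_train, target_test = _split_per_class(target_images, target_manifest, 8)
    stage_sets = [
        ArrayDataset(*datasets[0]),
        ArrayDataset(*datasets[1]),
        target_train,
    ]

    single = build_model(reduced_config(seed, seed), seed=seed)
    train_stage(single, stage_sets[0], stage_index=0, steps=TRANSFER_STEPS_PER_STAGE)
    single_report = _held_out_metrics(single, target_test)

    staged = build_model(reduced_config(seed, seed), seed=seed)
    for k, ds in enumerate(stage_sets):
        train_stage(staged, ds, stage_index=k, steps=TRANSFER_STEPS_PER_STAGE)
    staged_report = _held_out_metrics(staged, target_test)

    return {
        "single_stage_recall_at_1": single_report["recall_at_1"],
        "staged_recall_at_1": staged_report["recall_at_1"],
        "single_stage": single_report,
        "staged": staged_report,
        "n_test": target_test.n_images,
    }
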