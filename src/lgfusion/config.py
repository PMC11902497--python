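"""Structured configuration for the full model and training run.

One YAML file covers the backbone, neck, head, loss and training
sections; each section maps onto the dataclass owned by the respective
module.  Defaults reproduce the full-size model: a tiny-class backbone
(stage channels 96/192/384/768), 3 fusion layers at Cin=512, a 2048-d
GeM head (p=4.6), Sub-center ArcFace (m=17.2 deg, s=64, K=3) and AdamW
with cosine annealing from 5e-3 to 8e-5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .head import HeadConfig
from .losses import ArcFaceConfig
from .neck import NeckConfig

__all__ = ["TrainConfig", "ModelConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and data handling for one training run."""

    batch_size: int = 64
    epochs_per_stage: tuple[int, ...] = (60, 300, 300)
    lr_init: float = 5e-3
    lr_min: float = 8e-5
    weight_decay: float = 1e-2
    image_side: int = 224
    seed: int = 0
    max_steps_per_stage: int | None = None
    augment: bool = True
    pooled_stages: bool = False
    unfreeze_backbone: bool = False

    def __post_init__(self):
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    loss: ArcFaceConfig = field(default_factory=ArcFaceConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


_SECTIONS = {
    "backbone": BackboneConfig,
    "neck": NeckConfig,
    "head": HeadConfig,
    "loss": ArcFaceConfig,
    "train": TrainConfig,
}


def _build_section(cls, values: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for key, value in values.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def config_from_dict(raw: dict) -> ModelConfig:
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sections = {
        name: _build_section(cls, raw.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return ModelConfig(**sections)


def config_to_dict(cfg: ModelConfig) -> dict:
    return {name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS}


def load_config(path: str | Path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
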