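"""Shared fixtures: tiny seeded models and procedural datasets."""

import numpy as np
import pytest

from lgfusion import FixtureSpec, build_model, generate_texture_dataset
from lgfusion.backbone import BackboneConfig
from lgfusion.config import ModelConfig, TrainConfig
from lgfusion.data import ArrayDataset
from lgfusion.neck import NeckConfig

TINY_CHANNELS = (8, 16, 32, 64)


def tiny_config(num_layers=1, inner_channels=64, batch_size=8, seed=7, **train_kw):
    train_kw.setdefault("augment", False)
    return ModelConfig(
        backbone=BackboneConfig(
            variant_name="fixture-0", stage_channels=TINY_CHANNELS
        ),
        neck=NeckConfig(num_layers=num_layers, inner_channels=inner_channels),
        train=TrainConfig(batch_size=batch_size, seed=seed, **train_kw),
    )


@pytest.fixture(scope="session")
def fixture_data():
    """8-class, 12-per-class procedural texture set (arrays + manifest)."""
    spec = FixtureSpec(n_classes=8, n_per_class=12, image_side=64, seed=0)
    images, manifest = generate_texture_dataset(spec)
    return images, manifest


@pytest.fixture(scope="session")
def fixture_dataset(fixture_data):
    images, manifest = fixture_data
    return ArrayDataset(images, manifest)


@pytest.fixture()
def tiny_model():
    """Fresh 1-layer Cin=64 model on the seed-0 fixture backbone."""
    return build_model(tiny_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
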