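"""Training pipeline: schedules, determinism, checkpoints, counting."""

import numpy as np
import pytest

from lgfusion import (
    build_model,
    count_trainable_parameters,
    embed_dataset,
    load_checkpoint,
    run_strategy,
    save_checkpoint,
    train_stage,
)
from lgfusion.backbone import ConfigurationError
from lgfusion.config import ModelConfig
from lgfusion.data import ArrayDataset
from lgfusion.training import _weights_digest, augment_batch, pool_datasets

from conftest import tiny_config


def small_subset(fixture_dataset, per_class=4):
    manifest = fixture_dataset.manifest
    keep = manifest.index[manifest.groupby("class").cumcount() < per_class]
    return ArrayDataset(fixture_dataset.images[keep], manifest.loc[keep])


class TestTrainStage:
    def test_learning_rate_endpoints(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        _, hist = train_stage(model, small_subset(fixture_dataset, 2), steps=5)
        assert hist[0]["lr"] == 5e-3
        assert abs(hist[-1]["lr"] - 8e-5) < 1e-9

    def test_running_loss_decreases(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        _, hist = train_stage(model, small_subset(fixture_dataset), steps=40)
        losses = [h["loss"] for h in hist]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_same_seed_same_first_step_loss(self, fixture_dataset):
        ds = small_subset(fixture_dataset, 2)
        losses = []
        for _ in range(2):
            model = build_model(tiny_config(seed=9), seed=9)
            _, hist = train_stage(model, ds, steps=1)
            losses.append(hist[0]["loss"])
        assert losses[0] == losses[1]

    def test_frozen_backbone_weights_unchanged(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        before = _weights_digest(model.backbone)
        train_stage(model, small_subset(fixture_dataset, 2), steps=2)
        assert _weights_digest(model.backbone) == before

    def test_empty_dataset_rejected(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        import pandas as pd

        with pytest.raises(ValueError):
            ArrayDataset(np.zeros((0, 64, 64, 3)), pd.DataFrame(columns=["id", "class", "scan"]))


class TestStrategies:
    def test_strategy_a_is_single_stage(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        ds = small_subset(fixture_dataset, 2)
        _, prov = run_strategy("A", [ds], model, steps_per_stage=1)
        assert [p["stage"] for p in prov] == [0]

    def test_strategy_c_logs_three_stages_in_order(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        ds = small_subset(fixture_dataset, 2)
        _, prov = run_strategy("C", [ds, ds, ds], model, steps_per_stage=1)
        assert [p["stage"] for p in prov] == [0, 1, 2]

    def test_missing_stage_dataset_is_configuration_error(self, fixture_dataset):
        model = build_model(tiny_config(), seed=7)
        with pytest.raises(ConfigurationError, match="needs"):
            run_strategy("C", [small_subset(fixture_dataset, 2)], model)

    def test_pooled_mode_merges_classes(self, fixture_dataset):
        ds = small_subset(fixture_dataset, 2)
        pooled = pool_datasets([ds, ds])
        assert pooled.n_images == 2 * ds.n_images
        assert pooled.n_classes == 2 * ds.n_classes


class TestCheckpoint:
    def test_round_trip_embeddings_bit_identical(self, tmp_path, fixture_dataset):
        model = build_model(tiny_config(), seed=3)
        ds = small_subset(fixture_dataset, 2)
        train_stage(model, ds, steps=2)
        ids1, before = embed_dataset(model, ds)
        save_checkpoint(tmp_path / "ck.npz", model, [{"stage": 0}])
        restored, prov = load_checkpoint(tmp_path / "ck.npz")
        ids2, after = embed_dataset(restored, ds)
        assert ids1 == ids2
        np.testing.assert_array_equal(before, after)
        assert prov == [{"stage": 0}]

    def test_format_version_checked(self, tmp_path):
        import json

        model = build_model(tiny_config(), seed=3)
        save_checkpoint(tmp_path / "ck.npz", model)
        with np.load(tmp_path / "ck.npz") as archive:
            arrays = {k: archive[k] for k in archive.files}
        meta = json.loads(bytes(arrays["meta.json"]).decode())
        meta["format_version"] = 99
        arrays["meta.json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(tmp_path / "bad.npz", **arrays)
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(tmp_path / "bad.npz")


class TestParameterCounting:
    def test_tiny_config_matches_hand_audit(self):
        """Cin=8, r=2, 1 layer, laterals (8,16,32,64): audited shape-by-shape.

        laterals: (8+16+32+64)*8 + 4*8 = 992
        global unit: dw 8*9+8 + pw 4*8+4 + grn 2*4 + pw 8*4+8 + alpha = 165
        local unit:  pw 4*8+4 + pw 8*4+8 + alpha = 77
        layer: 6*165 + 8*77 + 14 fusion weights = 1620
        head: 4 * (1 + 2*(8*8+8)) = 580
        """
        cfg = tiny_config(inner_channels=8)
        model = build_model(cfg, seed=0)
        assert count_trainable_parameters(model) == 992 + 1620 + 580

    def test_doubling_layers_adds_one_layer_block(self):
        c1 = count_trainable_parameters(build_model(tiny_config(1), seed=0))
        c2 = count_trainable_parameters(build_model(tiny_config(2), seed=0))
        c3 = count_trainable_parameters(build_model(tiny_config(3), seed=0))
        assert c2 - c1 == c3 - c2 > 0

    def test_loss_bank_and_backbone_excluded(self):
        model = build_model(tiny_config(), seed=0)
        neck_head = count_trainable_parameters(model)
        assert count_trainable_parameters(model, scope="all") > neck_head


class TestEmbedding:
    def test_matrix_shape_and_rerun_identical(self, fixture_dataset):
        model = build_model(tiny_config(), seed=3)
        ds = small_subset(fixture_dataset, 2)
        ids, m1 = embed_dataset(model, ds)
        _, m2 = embed_dataset(model, ds)
        assert m1.shape == (ds.n_images, model.descriptor_dim)
        np.testing.assert_array_equal(m1, m2)
        assert ids == list(ds.ids)

    def test_strict_reader_aborts_on_corrupt_file(self, tmp_path):
        from lgfusion.data import ImageFolderDataset
        from lgfusion.fixtures import FixtureSpec, write_texture_dataset

        manifest = write_texture_dataset(FixtureSpec(2, 2, 32, seed=0), tmp_path)
        victim = tmp_path / manifest["path"].iloc[0]
        victim.write_bytes(b"not a png")
        ds = ImageFolderDataset(tmp_path / "manifest.csv", image_side=32)
        with pytest.raises(OSError, match=victim.name):
            ds.load([0])


def test_augmentation_preserves_range_and_shape(rng):
    images = rng.uniform(0, 1, (4, 32, 32, 3))
    out = augment_batch(images, rng)
    assert out.shape == images.shape
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert not np.array_equal(out, images)
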