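"""Backbone adapter: expose four multi-scale lateral feature maps.

Any stage-wise convolutional backbone can feed the fusion neck as long as
it produces four feature maps at strides 4, 8, 16 and 32 relative to the
input.  The adapter is variant-agnostic; the default configuration uses
tiny-class stage widths (96, 192, 384, 768).  A deterministic fixture
backbone (random, frozen, seed-reproducible) keeps the whole test surface
independent of pretrained downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Module, Parameter, Tensor, conv2d, no_grad

__all__ = [
    "BackboneConfig",
    "FeaturePyramid",
    "FixtureBackbone",
    "make_fixture_backbone",
    "extract_pyramid",
    "DimensionError",
    "ConfigurationError",
]

STAGE_STRIDES = (4, 8, 16, 32)


class DimensionError(ValueError):
    """An input or feature map violates a spatial-size contract."""


class ConfigurationError(ValueError):
    """A model configuration is inconsistent with the data it is given."""


@dataclass(frozen=True)
class BackboneConfig:
    """Static description of a stage-wise backbone.

    ``normalize_mean``/``normalize_std`` are per-channel RGB statistics in
    [0, 1] units; normalization is a property of the backbone, not of the
    pipeline.
    """

    variant_name: str = "convnext-tiny-class"
    stage_channels: tuple[int, int, int, int] = (96, 192, 384, 768)
    stage_strides: tuple[int, int, int, int] = STAGE_STRIDES
    frozen: bool = True
    normalize_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    normalize_std: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self):
        if tuple(self.stage_strides) != STAGE_STRIDES:
            raise ConfigurationError(
                f"stage_strides must be {STAGE_STRIDES}, got {self.stage_strides}"
            )
        if len(self.stage_channels) != 4 or any(c <= 0 for c in self.stage_channels):
            raise ConfigurationError("stage_channels must be 4 positive integers")
        if list(self.stage_channels) != sorted(self.stage_channels):
            raise ConfigurationError("stage_channels must be non-decreasing")


class FeaturePyramid:
    """Ordered set of 4 feature maps at strides 4, 8, 16, 32."""

    def __init__(self, levels: list[Tensor]):
        if len(levels) != 4:
            raise DimensionError(f"a pyramid has exactly 4 levels, got {len(levels)}")
        for i in range(3):
            ha, wa = levels[i].shape[-2:]
            hb, wb = levels[i + 1].shape[-2:]
            if ha != 2 * hb or wa != 2 * wb:
                raise DimensionError(
                    f"pyramid level {i + 1} must halve level {i} spatially: "
                    f"{(ha, wa)} vs {(hb, wb)}"
                )
        self.levels = list(levels)

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i: int) -> Tensor:
        return self.levels[i]

    def __len__(self) -> int:
        return 4

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(level.shape[1] for level in self.levels)

    @property
    def spatial_sizes(self) -> tuple[tuple[int, int], ...]:
        return tuple(tuple(level.shape[-2:]) for level in self.levels)


class FixtureBackbone(Module):
    """Tiny deterministic 4-stage strided convolutional feature extractor.

    Stage 1 is a 4x4/stride-4 patchify convolution; stages 2-4 are 3x3
    stride-2 convolutions, each followed by a GELU.  Weights are drawn once
    from a seeded generator, so two backbones built from the same seed are
    bit-identical.  The backbone is frozen by default: features are
    computed without building an autodiff tape.
    """

    def __init__(self, config: BackboneConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = config.stage_channels
        chain = [(3, c1, 4, 4, 0), (c1, c2, 3, 2, 1), (c2, c3, 3, 2, 1), (c3, c4, 3, 2, 1)]
        self.weights = []
        self.biases = []
        for cin, cout, k, _s, _p in chain:
            fan_in = cin * k * k
            w = rng.standard_normal((cout, cin, k, k)) / np.sqrt(fan_in)
            self.weights.append(Parameter(w))
            self.biases.append(Parameter(rng.standard_normal(cout) * 0.1))
        self._chain = chain

    def forward_stages(self, x: Tensor) -> list[Tensor]:
        maps = []
        h = x
        for (cin, cout, k, s, p), w, b in zip(self._chain, self.weights, self.biases):
            h = conv2d(h, w, b, stride=s, padding=p).gelu()
            maps.append(h)
        return maps


def make_fixture_backbone(
    seed: int, stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
) -> FixtureBackbone:
    """Build the deterministic tiny backbone used throughout the test suite."""
    cfg = BackboneConfig(
        variant_name=f"fixture-{seed}",
        stage_channels=tuple(stage_channels),
        frozen=True,
    )
    return FixtureBackbone(cfg, seed)


def _normalize(images: np.ndarray, cfg: BackboneConfig) -> np.ndarray:
    mean = np.asarray(cfg.normalize_mean, dtype=np.float64)
    std = np.asarray(cfg.normalize_std, dtype=np.float64)
    return (images - mean) / std


def extract_pyramid(images: np.ndarray, backbone) -> FeaturePyramid:
    """Run a batch of RGB images through a backbone and collect the pyramid.

    Parameters
    ----------
    images:
        Batch array of shape (N, H, W, 3) with pixel values in [0, 1].
        Images must be square with side divisible by 32.
    backbone:
        Any object with a ``config`` attribute (:class:`BackboneConfig`)
        and a ``forward_stages(Tensor) -> list[Tensor]`` method returning
        the four stage outputs in stride order.

    Returns
    -------
    FeaturePyramid
        Four NCHW feature maps with the configured stage channels.  When
        the backbone is frozen no gradient flows into its weights.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise DimensionError(f"expected (N, H, W, 3) images, got {images.shape}")
    n, h, w, _ = images.shape
    if h != w:
        raise DimensionError(f"images must be square, got {h}x{w}")
    if h % 32:
        raise DimensionError(f"image side {h} is not divisible by 32")
    cfg: BackboneConfig = backbone.config
    x = Tensor(np.ascontiguousarray(_normalize(images, cfg).transpose(0, 3, 1, 2)))
    if cfg.frozen:
        with no_grad():
            maps = backbone.forward_stages(x)
        maps = [m.detach() for m in maps]
    else:
        maps = backbone.forward_stages(x)
    for i, (m, c_exp, s) in enumerate(zip(maps, cfg.stage_channels, cfg.stage_strides)):
        if m.shape[1] != c_exp:
            raise ConfigurationError(
                f"stage {i} produced {m.shape[1]} channels, config says {c_exp}"
            )
        if m.shape[-2:] != (h // s, w // s):
            raise DimensionError(
                f"stage {i} spatial size {m.shape[-2:]} != {(h // s, w // s)}"
            )
    return FeaturePyramid(maps)
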