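"""Local-Global Feature Fusion Neck.

One neck layer takes a 4-level feature pyramid (P1_0 .. P4_0, strides 4 to
32, all at the inner channel width) and produces a fused pyramid through
six fusion nodes arranged as a bidirectional top-down / bottom-up pass:

    P3_1 = fuse( GA(P3_0),      LA(up(P4_0)) )
    P2_1 = fuse( GA(P2_0),      LA(up(P3_1)) )
    P1_2 = fuse( GA(P1_0),      LA(up(P2_1)) )
    P2_2 = fuse( LA(P2_0), LA(P2_1), GA(down(P1_2)) )
    P3_2 = fuse( LA(P3_0), LA(P3_1), GA(down(P2_2)) )
    P4_2 = fuse( LA(P4_0),      GA(down(P3_2)) )

``fuse`` is Fast Normalized Fusion: a weighted average with trainable
weights passed through a relu and normalized by their sum plus a small
epsilon.  Every input edge owns its private aggregator unit (no weight
sharing across edges or layers).  ``up`` is nearest-neighbour 2x
upsampling, ``down`` 2x2 max pooling.  Stacking layers feeds one layer's
terminal nodes to the next as its P*_0 inputs; a per-level 1x1 lateral
projection reconciles backbone channels with the inner width once, before
the first layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregators import GlobalAggregator, LocalAggregator
from .autodiff import (
    Module,
    Parameter,
    Tensor,
    conv2d,
    max_pool2x2,
    upsample_nearest2x,
)
from .backbone import ConfigurationError, DimensionError, FeaturePyramid

__all__ = [
    "NeckConfig",
    "FusionNode",
    "FuseLayer",
    "Neck",
    "fast_normalized_fuse",
    "resize_to",
]

NODE_IDS = ("3_1", "2_1", "1_2", "2_2", "3_2", "4_2")

# aggregator flavour per input edge of each node ("g" global, "l" local),
# in the argument order of the node equations above
NODE_EDGE_KINDS = {
    "3_1": ("g", "l"),
    "2_1": ("g", "l"),
    "1_2": ("g", "l"),
    "2_2": ("l", "l", "g"),
    "3_2": ("l", "l", "g"),
    "4_2": ("l", "g"),
}


@dataclass(frozen=True)
class NeckConfig:
    """Hyperparameters of the fusion neck.

    inner_channels (Cin) is the uniform channel width of the neck; the
    defaults (3 layers, Cin=512, r=2, eps=1e-4) give the full-size model.
    """

    num_layers: int = 3
    inner_channels: int = 512
    reduction_r: int = 2
    fusion_epsilon: float = 1e-4
    resize_up: str = "nearest"
    resize_down: str = "maxpool"
    activation: str = "gelu"

    def __post_init__(self):
        if self.num_layers < 1:
            raise ConfigurationError("num_layers must be >= 1")
        if self.inner_channels % self.reduction_r:
            raise ConfigurationError(
                f"inner_channels {self.inner_channels} not divisible by "
                f"reduction_r {self.reduction_r}"
            )
        if self.resize_up not in ("nearest",):
            raise ConfigurationError(f"unknown resize_up {self.resize_up!r}")
        if self.resize_down not in ("maxpool",):
            raise ConfigurationError(f"unknown resize_down {self.resize_down!r}")


def fast_normalized_fuse(inputs: list[Tensor], weights: Tensor, eps: float) -> Tensor:
    """Relu-weighted average: sum_j relu(w_j) I_j / (sum_j relu(w_j) + eps)."""
    inputs = [Tensor._lift(x) for x in inputs]
    weights = Tensor._lift(weights)
    shapes = {tuple(t.shape) for t in inputs}
    if len(shapes) != 1:
        raise DimensionError(f"fusion inputs disagree in shape: {sorted(shapes)}")
    if weights.shape != (len(inputs),):
        raise DimensionError(
            f"need {len(inputs)} fusion weights, got shape {weights.shape}"
        )
    w = weights.relu()
    total = w.sum() + eps
    acc = None
    for j, x in enumerate(inputs):
        mask = np.zeros(len(inputs))
        mask[j] = 1.0
        wj = (w * mask).sum()
        term = x * wj
        acc = term if acc is None else acc + term
    return acc * (1.0 / total)


def resize_to(x: Tensor, target_hw: tuple[int, int], mode: str = "auto") -> Tensor:
    """Resize a feature map by exactly 2x up or down.

    Upsampling uses nearest-neighbour interpolation, downsampling 2x2 max
    pooling with stride 2; channels are unchanged.  Any other size ratio
    is rejected.
    """
    h, w = x.shape[-2:]
    th, tw = target_hw
    if (th, tw) == (2 * h, 2 * w):
        return upsample_nearest2x(x)
    if (h, w) == (2 * th, 2 * tw):
        return max_pool2x2(x)
    raise DimensionError(
        f"resize supports exact 2x ratios only: {h}x{w} -> {th}x{tw}"
    )


class FusionNode(Module):
    """One fusion point: per-edge aggregators plus Fast Normalized Fusion."""

    def __init__(self, node_id: str, cfg: NeckConfig, rng: np.random.Generator):
        if node_id not in NODE_EDGE_KINDS:
            raise ConfigurationError(f"unknown fusion node {node_id!r}")
        kinds = NODE_EDGE_KINDS[node_id]
        self.node_id = node_id
        self.weights = Parameter(np.ones(len(kinds)))
        self.aggregators = [
            (GlobalAggregator if k == "g" else LocalAggregator)(
                cfg.inner_channels, cfg.reduction_r, cfg.activation, rng
            )
            for k in kinds
        ]
        self.eps = cfg.fusion_epsilon

    def forward(self, inputs: list[Tensor]) -> Tensor:
        if len(inputs) != len(self.aggregators):
            raise DimensionError(
                f"node {self.node_id} expects {len(self.aggregators)} inputs, "
                f"got {len(inputs)}"
            )
        try:
            gated = [agg(x) for agg, x in zip(self.aggregators, inputs)]
            return fast_normalized_fuse(gated, self.weights, self.eps)
        except (DimensionError, ConfigurationError) as exc:
            raise type(exc)(f"node {self.node_id}: {exc}") from exc


class FuseLayer(Module):
    """One full six-node neck layer."""

    def __init__(self, cfg: NeckConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.nodes = [FusionNode(nid, cfg, rng) for nid in NODE_IDS]
        self._by_id = {n.node_id: n for n in self.nodes}

    def node(self, node_id: str) -> FusionNode:
        return self._by_id[node_id]

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        cin = self.cfg.inner_channels
        for i, level in enumerate(pyr):
            if level.shape[1] != cin:
                raise ConfigurationError(
                    f"neck layer expects {cin} channels at level {i}, "
                    f"got {level.shape[1]}"
                )
        p1_0, p2_0, p3_0, p4_0 = pyr
        up = lambda x: resize_to(x, (2 * x.shape[-2], 2 * x.shape[-1]))
        down = lambda x: resize_to(x, (x.shape[-2] // 2, x.shape[-1] // 2))
        node = self._by_id
        # top-down pass through the intermediate nodes ...
        p3_1 = node["3_1"]([p3_0, up(p4_0)])
        p2_1 = node["2_1"]([p2_0, up(p3_1)])
        p1_2 = node["1_2"]([p1_0, up(p2_1)])
        # ... then bottom-up through the terminal nodes (P2_1 and P3_1 are
        # reused here, which is what makes the layer bidirectional)
        p2_2 = node["2_2"]([p2_0, p2_1, down(p1_2)])
        p3_2 = node["3_2"]([p3_0, p3_1, down(p2_2)])
        p4_2 = node["4_2"]([p4_0, down(p3_2)])
        return FeaturePyramid([p1_2, p2_2, p3_2, p4_2])


class Neck(Module):
    """Lateral projections plus a stack of fusion layers.

    The 1x1 lateral projections (with bias) map the backbone stage
    channels to the inner width once; every subsequent layer consumes the
    previous layer's terminal nodes directly.  Layer parameters are
    unshared.
    """

    def __init__(
        self,
        stage_channels: tuple[int, int, int, int],
        cfg: NeckConfig,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.cfg = cfg
        cin = cfg.inner_channels
        self.lateral_weights = [
            Parameter(rng.standard_normal((cin, c, 1, 1)) / np.sqrt(c))
            for c in stage_channels
        ]
        self.lateral_biases = [Parameter(np.zeros(cin)) for _ in stage_channels]
        self.layers = [FuseLayer(cfg, rng) for _ in range(cfg.num_layers)]

    def project_laterals(self, pyr: FeaturePyramid) -> FeaturePyramid:
        projected = [
            conv2d(level, w, b)
            for level, w, b in zip(pyr, self.lateral_weights, self.lateral_biases)
        ]
        return FeaturePyramid(projected)

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        out = self.project_laterals(pyr)
        for layer in self.layers:
            out = layer(out)
        return out
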