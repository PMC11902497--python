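"""Global/Local Feature Aggregator units.

The fusion neck gates every incoming feature map with a channel-attention
unit.  Two flavours exist:

* the *global* unit models spatial context with a depthwise 3x3
  convolution and re-normalizes channel responses with Global Response
  Normalization (GRN) inside a squeeze bottleneck:
  ``G(X) = PW(GRN(act(PW(DW(X)))))``;
* the *local* unit is the same bottleneck without the spatial and
  normalization stages: ``L(X) = PW(act(PW(X)))``.

Both are blended with the identity through a single trainable scalar
``alpha``::

    GA(X) = alpha * X + (1 - alpha) * X * sigmoid(G(X))
    LA(X) = alpha * X + (1 - alpha) * X * sigmoid(L(X))

The point-wise convolutions squeeze C channels down to C/r and back; r is
the channel reduction factor (2 by default).  All stages preserve the
input shape, so the sigmoid gate acts per element.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Module, Parameter, Tensor, conv2d
from .backbone import ConfigurationError

__all__ = [
    "GRN",
    "GlobalAggregator",
    "LocalAggregator",
    "ACTIVATIONS",
]

# activation delta of the bottleneck; GELU by default, matching the
# convnext-style backbones the unit is designed to sit behind
ACTIVATIONS = {
    "gelu": lambda t: t.gelu(),
    "relu": lambda t: t.relu(),
    "sigmoid": lambda t: t.sigmoid(),
    "identity": lambda t: t,
}


class GRN(Module):
    """Global Response Normalization with identity residual.

    Per channel c the spatial L2 norm ``G_c = ||x_c||_2`` is computed, then
    divisively normalized by the cross-channel mean ``N_c = G_c /
    (mean_c G_c + eps)``, and the input is re-scaled:

        y = gamma * (x * N_c) + beta + x

    gamma and beta are trainable per-channel vectors initialized at zero,
    so a fresh GRN is the identity map.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        self.gamma = Parameter(np.zeros(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = float(eps)

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, C, H, W); tiny floor keeps the sqrt differentiable at 0
        norm = ((x * x).sum(axis=(2, 3), keepdims=True) + 1e-24) ** 0.5  # (N,C,1,1)
        scale = norm / (norm.mean(axis=1, keepdims=True) + self.eps)
        gamma = self.gamma.reshape(1, -1, 1, 1)
        beta = self.beta.reshape(1, -1, 1, 1)
        return gamma * (x * scale) + beta + x


class _AggregatorBase(Module):
    def __init__(self, channels: int, reduction_r: int, activation: str, rng: np.random.Generator):
        if channels % reduction_r:
            raise ConfigurationError(
                f"channels {channels} not divisible by reduction factor {reduction_r}"
            )
        if activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {activation!r}")
        self.channels = int(channels)
        self.reduction_r = int(reduction_r)
        self.activation = activation
        reduced = channels // reduction_r
        self.alpha = Parameter(0.5)
        # 1x1 squeeze / expand point-wise convolutions, with bias
        self.pw1_weight = Parameter(
            rng.standard_normal((reduced, channels, 1, 1)) / np.sqrt(channels)
        )
        self.pw1_bias = Parameter(np.zeros(reduced))
        self.pw2_weight = Parameter(
            rng.standard_normal((channels, reduced, 1, 1)) / np.sqrt(reduced)
        )
        self.pw2_bias = Parameter(np.zeros(channels))

    def _check(self, x: Tensor) -> None:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"aggregator built for {self.channels} channels got {x.shape[1]}"
            )

    def operator(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        """alpha-blend of identity and sigmoid-gated operator output."""
        self._check(x)
        gate = self.operator(x).sigmoid()
        return self.alpha * x + (1.0 - self.alpha) * (x * gate)


class GlobalAggregator(_AggregatorBase):
    """Channel attention with spatial context (depthwise conv) and GRN."""

    def __init__(self, channels: int, reduction_r: int = 2,
                 activation: str = "gelu", rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        super().__init__(channels, reduction_r, activation, rng)
        self.dw_weight = Parameter(
            rng.standard_normal((channels, 1, 3, 3)) / 3.0
        )
        self.dw_bias = Parameter(np.zeros(channels))
        self.grn = GRN(channels // reduction_r)

    def operator(self, x: Tensor) -> Tensor:
        """G(X) = PW(GRN(act(PW(DW(X)))))."""
        self._check(x)
        act = ACTIVATIONS[self.activation]
        h = conv2d(x, self.dw_weight, self.dw_bias, padding=1, groups=self.channels)
        h = conv2d(h, self.pw1_weight, self.pw1_bias)
        h = self.grn(act(h))
        return conv2d(h, self.pw2_weight, self.pw2_bias)


class LocalAggregator(_AggregatorBase):
    """Channel attention from the point-wise bottleneck alone."""

    def __init__(self, channels: int, reduction_r: int = 2,
                 activation: str = "gelu", rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        super().__init__(channels, reduction_r, activation, rng)

    def operator(self, x: Tensor) -> Tensor:
        """L(X) = PW(act(PW(X)))."""
        self._check(x)
        act = ACTIVATIONS[self.activation]
        h = conv2d(x, self.pw1_weight, self.pw1_bias)
        return conv2d(act(h), self.pw2_weight, self.pw2_bias)
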