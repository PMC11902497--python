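"""GeM-based embedding head.

Each of the four terminal pyramid levels feeds its own *mini-head*:
generalized-mean (GeM) pooling with a trainable exponent, a fully
connected layer, L2 normalization, and a second fully connected layer,
producing a vector of length Cin.  The four vectors are stacked into the
final image descriptor of length 4*Cin (2048 at the default Cin=512),
which is L2-normalized so that Euclidean ranking on descriptors equals
cosine ranking — the convention both the angular-margin loss and the
Euclidean retrieval index rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Linear, Module, Parameter, Tensor, concatenate, l2_normalize
from .backbone import ConfigurationError, DimensionError, FeaturePyramid

__all__ = ["HeadConfig", "gem_pool", "MiniHead", "GemHead", "assemble_descriptor"]


@dataclass(frozen=True)
class HeadConfig:
    """GeM head hyperparameters.

    ``gem_p`` is the pooling exponent (1 = average pooling, large p
    approaches max pooling); ``gem_eps`` is the clamp floor applied to
    activations before exponentiation; ``normalize_final`` controls the
    final L2 normalization of the stacked descriptor.
    """

    gem_p: float = 4.6
    gem_eps: float = 1e-6
    normalize_final: bool = True

    def __post_init__(self):
        if self.gem_p <= 0:
            raise ConfigurationError(f"GeM exponent must be positive, got {self.gem_p}")
        if self.gem_p < 1:
            raise ConfigurationError(
                f"GeM exponent below 1 at initialization is not supported ({self.gem_p})"
            )


def gem_pool(x: Tensor, p, eps: float = 1e-6) -> Tensor:
    """Generalized-mean pooling over the spatial axes of an NCHW map.

    Per channel: ``( mean_{h,w} clamp(x, eps)^p )^(1/p)``.  ``p`` may be a
    float or a scalar trainable tensor; gradients flow through both the
    activations and the exponent.
    """
    if not isinstance(p, Tensor):
        if p <= 0:
            raise ConfigurationError(f"GeM exponent must be positive, got {p}")
        p = Tensor(float(p))
    elif float(p.data) <= 0:
        raise ConfigurationError(f"GeM exponent must be positive, got {float(p.data)}")
    clamped = x.clamp_min(float(eps))
    powered = (clamped.log() * p).exp()          # clamp keeps the log in domain
    mean = powered.mean(axis=(2, 3))             # (N, C)
    return (mean.log() * (1.0 / p)).exp()


class MiniHead(Module):
    """GeM -> FC -> L2-normalize -> FC, emitting a Cin-length vector."""

    def __init__(self, channels: int, cfg: HeadConfig, rng: np.random.Generator):
        self.channels = int(channels)
        self.gem_p = Parameter(cfg.gem_p)
        self.gem_eps = cfg.gem_eps
        self.fc1 = Linear(channels, channels, rng)
        self.fc2 = Linear(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise DimensionError(
                f"mini-head built for {self.channels} channels got {x.shape[1]}"
            )
        v = gem_pool(x, self.gem_p, self.gem_eps)
        v = self.fc1(v)
        v = l2_normalize(v, axis=1)
        return self.fc2(v)


def assemble_descriptor(vectors: list[Tensor], normalize: bool = True) -> Tensor:
    """Stack the four mini-head vectors into the final descriptor.

    Concatenation follows pyramid-level order (P1_2 .. P4_2); the result
    is L2-normalized unless ``normalize`` is off.
    """
    lengths = {v.shape[-1] for v in vectors}
    if len(lengths) != 1:
        raise DimensionError(f"mini-head vectors disagree in length: {sorted(lengths)}")
    fe = concatenate(vectors, axis=-1)
    return l2_normalize(fe, axis=-1) if normalize else fe


class GemHead(Module):
    """Four mini-heads plus descriptor assembly; output length 4*Cin."""

    def __init__(self, channels: int, cfg: HeadConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.cfg = cfg
        self.mini_heads = [MiniHead(channels, cfg, rng) for _ in range(4)]

    @property
    def descriptor_dim(self) -> int:
        return 4 * self.mini_heads[0].channels

    def forward(self, pyr: FeaturePyramid) -> Tensor:
        vectors = [head(level) for head, level in zip(self.mini_heads, pyr)]
        return assemble_descriptor(vectors, normalize=self.cfg.normalize_final)
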