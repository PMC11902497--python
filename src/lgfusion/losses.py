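"""Sub-center ArcFace loss.

Classification-supervised metric learning: each class owns K trainable
sub-centers; an embedding's similarity to a class is the maximum cosine
over that class's sub-centers.  The target class's angle is enlarged by an
additive margin m before the softmax cross-entropy over scaled logits:

    logit_y = s * cos(theta_y + m),   logit_j = s * cos(theta_j)  (j != y)

m is stored in degrees (default 17.2, about 0.300 rad) and converted at
use; s is the logit scale (default 64).  Embeddings must arrive
L2-normalized — the head guarantees this — and sub-centers are
re-normalized at every use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Module, Parameter, Tensor, l2_normalize
from .backbone import ConfigurationError

__all__ = ["ArcFaceConfig", "SubcenterArcFace", "subcenter_cosines", "arcface_loss"]

_COS_CLIP = 1e-7


@dataclass(frozen=True)
class ArcFaceConfig:
    """Margin in DEGREES (17.2 deg ~= 0.300 rad), scale, and sub-center count."""

    margin_deg: float = 17.2
    scale_s: float = 64.0
    num_subcenters: int = 3

    def __post_init__(self):
        m_rad = math.radians(self.margin_deg)
        if not 0.0 <= m_rad < math.pi / 2:
            raise ConfigurationError(
                f"margin must lie in [0, 90) degrees, got {self.margin_deg}"
            )
        if self.scale_s <= 0:
            raise ConfigurationError(f"scale must be positive, got {self.scale_s}")
        if self.num_subcenters < 1:
            raise ConfigurationError("need at least one sub-center per class")


def subcenter_cosines(embeddings: Tensor, centers: Tensor, num_classes: int) -> Tensor:
    """Best sub-center cosine per class.

    ``embeddings``: (B, D), unit-norm (deviation beyond 1e-3 is a contract
    violation).  ``centers``: (num_classes * K, D) or (num_classes, K, D);
    rows are L2-normalized at use.  Returns (B, num_classes).
    """
    embeddings = Tensor._lift(embeddings)
    centers = Tensor._lift(centers)
    norms = np.linalg.norm(embeddings.data, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"embeddings must be unit-norm for cosine logits (max deviation {worst:.2e})"
        )
    if centers.ndim == 3:
        centers = centers.reshape(centers.shape[0] * centers.shape[1], centers.shape[2])
    total, dim = centers.shape
    if total % num_classes:
        raise ConfigurationError(
            f"{total} sub-centers do not divide into {num_classes} classes"
        )
    k = total // num_classes
    centers_n = l2_normalize(centers, axis=-1)
    cos_all = embeddings @ centers_n.transpose(1, 0)          # (B, classes*K)
    cos_all = cos_all.reshape(embeddings.shape[0], num_classes, k)
    return cos_all.max(axis=2)


def arcface_loss(cosines: Tensor, labels: np.ndarray, cfg: ArcFaceConfig) -> Tensor:
    """Mean additive-angular-margin cross-entropy over a batch.

    The target cosine is replaced by cos(theta + m) computed via the angle
    addition identity on cosines clipped to the open interval (-1, 1); the
    margin is applied unconditionally (no easy-margin variant).
    """
    cosines = Tensor._lift(cosines)
    labels = np.asarray(labels)
    batch, num_classes = cosines.shape
    if labels.shape != (batch,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {batch}")
    if labels.min() < 0 or labels.max() >= num_classes:
        raise IndexError(
            f"label out of range [0, {num_classes}): {labels.min()}..{labels.max()}"
        )
    m = math.radians(cfg.margin_deg)
    onehot = np.zeros((batch, num_classes))
    onehot[np.arange(batch), labels] = 1.0
    c = cosines.clip(-1.0 + _COS_CLIP, 1.0 - _COS_CLIP)
    sin = (1.0 - c * c) ** 0.5
    cos_margined = c * math.cos(m) - sin * math.sin(m)   # cos(theta + m)
    logits = cosines + onehot * (cos_margined - cosines)
    logits = logits * cfg.scale_s
    # numerically stable log-softmax; the shift is a constant w.r.t. the tape
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    log_probs = z - log_norm
    nll = -(log_probs * onehot).sum(axis=1)
    return nll.mean()


class SubcenterArcFace(Module):
    """Trainable sub-center bank plus the margin loss, as one module."""

    def __init__(
        self,
        num_classes: int,
        embed_dim: int,
        cfg: ArcFaceConfig | None = None,
        rng: np.random.Generator | None = None,
    ):
        cfg = cfg if cfg is not None else ArcFaceConfig()
        rng = rng if rng is not None else np.random.default_rng()
        self.cfg = cfg
        self.num_classes = int(num_classes)
        self.embed_dim = int(embed_dim)
        self.centers = Parameter(
            rng.standard_normal((num_classes * cfg.num_subcenters, embed_dim))
            / math.sqrt(embed_dim)
        )

    def cosines(self, embeddings: Tensor) -> Tensor:
        return subcenter_cosines(embeddings, self.centers, self.num_classes)

    def forward(self, embeddings: Tensor, labels: np.ndarray) -> Tensor:
        return arcface_loss(self.cosines(embeddings), labels, self.cfg)
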