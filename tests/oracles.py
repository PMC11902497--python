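"""Independent plain-numpy transcriptions of the model's operators.

These helpers re-derive every fusion-path operation directly from its
mathematical definition (loops and explicit broadcasting, no shared code
with the package's autodiff layer) so tests can compare the
implementation against a second, straight-line route.
"""

import math

import numpy as np
from scipy.special import erf


def np_sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def np_gelu(z):
    return 0.5 * z * (1.0 + erf(z / math.sqrt(2.0)))


def np_pointwise(x, w, b):
    # w: (O, C, 1, 1)
    return np.einsum("oc,nchw->nohw", w[:, :, 0, 0], x) + b[None, :, None, None]


def np_depthwise3x3(x, w, b):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            out += xp[:, :, i : i + h, j : j + wd] * w[None, :, 0, i, j, None, None]
    return out + b[None, :, None, None]


def np_grn(x, gamma, beta, eps=1e-6):
    norm = np.sqrt((x ** 2).sum(axis=(2, 3), keepdims=True))
    scale = norm / (norm.mean(axis=1, keepdims=True) + eps)
    return gamma[None, :, None, None] * (x * scale) + beta[None, :, None, None] + x


def np_global_operator(x, unit):
    h = np_depthwise3x3(x, unit.dw_weight.data, unit.dw_bias.data)
    h = np_pointwise(h, unit.pw1_weight.data, unit.pw1_bias.data)
    h = np_grn(np_gelu(h), unit.grn.gamma.data, unit.grn.beta.data)
    return np_pointwise(h, unit.pw2_weight.data, unit.pw2_bias.data)


def np_local_operator(x, unit):
    h = np_pointwise(x, unit.pw1_weight.data, unit.pw1_bias.data)
    return np_pointwise(np_gelu(h), unit.pw2_weight.data, unit.pw2_bias.data)


def np_aggregate(x, unit, operator):
    alpha = float(unit.alpha.data)
    return alpha * x + (1.0 - alpha) * x * np_sigmoid(operator(x, unit))


def np_global_aggregator(x, unit):
    return np_aggregate(x, unit, np_global_operator)


def np_local_aggregator(x, unit):
    return np_aggregate(x, unit, np_local_operator)


def np_fast_fuse(inputs, weights, eps):
    w = np.maximum(np.asarray(weights, dtype=float), 0.0)
    num = sum(wj * xj for wj, xj in zip(w, inputs))
    return num / (w.sum() + eps)


def np_upsample2x(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def np_downsample2x(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))


def np_fuse_layer(pyr, layer):
    """Straight-line transcription of the six fusion-node equations."""
    p1_0, p2_0, p3_0, p4_0 = pyr
    eps = layer.cfg.fusion_epsilon

    def node(nid, inputs, ops):
        n = layer.node(nid)
        gated = [op(x, agg) for x, agg, op in zip(inputs, n.aggregators, ops)]
        return np_fast_fuse(gated, n.weights.data, eps)

    ga, la = np_global_aggregator, np_local_aggregator
    p3_1 = node("3_1", [p3_0, np_upsample2x(p4_0)], [ga, la])
    p2_1 = node("2_1", [p2_0, np_upsample2x(p3_1)], [ga, la])
    p1_2 = node("1_2", [p1_0, np_upsample2x(p2_1)], [ga, la])
    p2_2 = node("2_2", [p2_0, p2_1, np_downsample2x(p1_2)], [la, la, ga])
    p3_2 = node("3_2", [p3_0, p3_1, np_downsample2x(p2_2)], [la, la, ga])
    p4_2 = node("4_2", [p4_0, np_downsample2x(p3_2)], [la, ga])
    return [p1_2, p2_2, p3_2, p4_2]


def np_gem(x, p, eps=1e-6):
    clamped = np.maximum(x, eps)
    return (np.mean(clamped ** p, axis=(2, 3))) ** (1.0 / p)
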