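"""Reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tape-based engine providing exactly the
operations the embedding model needs: broadcast-aware arithmetic, matrix
multiplication, grouped 2-D convolution, 2x2 max pooling, nearest-neighbour
2x upsampling, reductions, and the elementwise nonlinearities used by the
fusion neck and head.  All tensors are float64.

Design notes
------------
* ``Tensor`` wraps an ndarray plus an optional backward closure; calling
  :meth:`Tensor.backward` on a scalar runs the tape in reverse topological
  order and accumulates ``.grad`` on every tensor that requires gradients.
* ``Parameter`` is a ``Tensor`` that always requires gradients, regardless
  of the :func:`no_grad` context active at construction time.
* Gradients are plain ndarrays; optimizers mutate ``Parameter.data`` in
  place so that module references stay valid.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "AdamW",
    "no_grad",
    "concatenate",
    "conv2d",
    "max_pool2x2",
    "upsample_nearest2x",
    "l2_normalize",
    "cosine_annealed_lr",
]

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 ndarray with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators instead of treating a
    # Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction --------------------------------------------
    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def _accumulate(self, grad: np.ndarray) -> None:
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = _result(np.add(self.data, other.data), (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _result(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = _result(np.multiply(self.data, other.data), (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = _result(np.divide(self.data, other.data), (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(
                        _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)
                    )
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = _result(self.data ** exponent, (self,))
        if out.requires_grad:
            def bwd(g, a=self, e=exponent):
                a._accumulate(g * e * (a.data ** (e - 1.0)))
            out._backward = bwd
        return out

    # -- elementwise functions ------------------------------------------
    def exp(self):
        out = _result(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, o=out: a._accumulate(g * o.data)
        return out

    def log(self):
        out = _result(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(g / a.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        out = _result(data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, o=out: a._accumulate(
                g * o.data * (1.0 - o.data)
            )
        return out

    def relu(self):
        out = _result(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(g * (a.data > 0.0))
        return out

    def gelu(self):
        """Exact Gaussian-error-linear unit, 0.5*x*(1+erf(x/sqrt(2)))."""
        cdf = 0.5 * (1.0 + erf(self.data / math.sqrt(2.0)))
        out = _result(self.data * cdf, (self,))
        if out.requires_grad:
            def bwd(g, a=self, c=cdf):
                pdf = np.exp(-0.5 * a.data ** 2) / math.sqrt(2.0 * math.pi)
                a._accumulate(g * (c + a.data * pdf))
            out._backward = bwd
        return out

    def clamp_min(self, floor: float):
        """Elementwise max(x, floor); subgradient 1 where x > floor."""
        out = _result(np.maximum(self.data, floor), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, f=floor: a._accumulate(
                g * (a.data > f)
            )
        return out

    def clip(self, low: float, high: float):
        out = _result(np.clip(self.data, low, high), (self,))
        if out.requires_grad:
            def bwd(g, a=self, lo=low, hi=high):
                a._accumulate(g * ((a.data > lo) & (a.data < hi)))
            out._backward = bwd
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _result(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(
                g.reshape(a.data.shape)
            )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        out = _result(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, inv=inverse: a._accumulate(
                g.transpose(inv)
            )
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _result(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    axes = ax if isinstance(ax, tuple) else (ax,)
                    g = np.expand_dims(g, axes)
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties share the gradient equally."""
        maxed = self.data.max(axis=axis, keepdims=True)
        out_data = maxed if keepdims else maxed.squeeze(axis)
        out = _result(out_data, (self,))
        if out.requires_grad:
            mask = (self.data == maxed).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)

            def bwd(g, a=self, m=mask, ax=axis, kd=keepdims):
                if not kd:
                    g = np.expand_dims(g, ax)
                a._accumulate(g * m)
            out._backward = bwd
        return out

    def matmul(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = _result(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)
            out._backward = bwd
        return out

    __matmul__ = matmul


def _result(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data)
    if req:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


class Parameter(Tensor):
    """A trainable tensor; always requires gradients."""

    def __init__(self, data):
        super().__init__(data, requires_grad=False)
        self.requires_grad = True  # independent of any no_grad context


# ---------------------------------------------------------------------------
# structured operations
# ---------------------------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = _result(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g, ts=tensors, off=offsets, ax=axis):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[ax] = slice(off[i], off[i + 1])
                    t._accumulate(g[tuple(sl)])
        out._backward = bwd
    return out


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D convolution (cross-correlation) on NCHW tensors.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).  Depthwise
    convolution is ``groups == C_in`` with C_out == C_in.
    """
    x = Tensor._lift(x)
    n, cin, h, w = x.data.shape
    cout, cg, kh, kw = weight.data.shape
    if cin != cg * groups or cout % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight {weight.data.shape}, "
            f"groups {groups}"
        )
    s, p = int(stride), int(padding)
    if kh == 1 and kw == 1 and groups == 1 and s == 1 and p == 0:
        return _conv1x1(x, weight, bias, n, cin, cout, h, w)
    if groups == cin and cout == cin and s == 1:
        return _conv_depthwise(x, weight, bias, p)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    og = cout // groups
    win_g = win.reshape(n, groups, cg, ho, wo, kh, kw)
    w_g = weight.data.reshape(groups, og, cg, kh, kw)
    out_data = np.einsum(
        "ngchwij,gocij->ngohw", win_g, w_g, optimize=True
    ).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _result(out_data, parents)
    if out.requires_grad:
        def bwd(g):
            g_g = g.reshape(n, groups, og, ho, wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.einsum(
                    "ngohw,ngchwij->gocij", g_g, win_g, optimize=True
                )
                weight._accumulate(dw.reshape(cout, cg, kh, kw))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                dxp_g = dxp.reshape(n, groups, cg, *xp.shape[2:])
                for i in range(kh):
                    for j in range(kw):
                        tap = np.einsum(
                            "ngohw,goc->ngchw", g_g, w_g[:, :, :, i, j],
                            optimize=True,
                        )
                        dxp_g[:, :, :, i : i + s * ho : s, j : j + s * wo : s] += tap
                if p:
                    x._accumulate(dxp[:, :, p : p + h, p : p + w])
                else:
                    x._accumulate(dxp)
        out._backward = bwd
    return out


def _conv1x1(x, weight, bias, n, cin, cout, h, w):
    """Point-wise convolution as a batched BLAS matmul."""
    w2d = weight.data.reshape(cout, cin)
    xm = x.data.reshape(n, cin, h * w)
    out_data = (w2d @ xm).reshape(n, cout, h, w)
    if bias is not None:
        out_data += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _result(out_data, parents)
    if out.requires_grad:
        def bwd(g):
            gm = g.reshape(n, cout, h * w)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.einsum("noh,nch->oc", gm, xm, optimize=True)
                weight._accumulate(dw.reshape(cout, cin, 1, 1))
            if x.requires_grad:
                x._accumulate((w2d.T @ gm).reshape(n, cin, h, w))
        out._backward = bwd
    return out


def _conv_depthwise(x, weight, bias, p):
    """Depthwise kxk stride-1 convolution via per-tap slicing."""
    n, c, h, w = x.data.shape
    kh, kw = weight.data.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out_data = np.zeros((n, c, ho, wo))
    wd = weight.data[:, 0]  # (C, kh, kw)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, :, i : i + ho, j : j + wo] * wd[None, :, i, j, None, None]
    if bias is not None:
        out_data += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _result(out_data, parents)
    if out.requires_grad:
        def bwd(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.empty((c, 1, kh, kw))
                for i in range(kh):
                    for j in range(kw):
                        dw[:, 0, i, j] = (
                            g * xp[:, :, i : i + ho, j : j + wo]
                        ).sum(axis=(0, 2, 3))
                weight._accumulate(dw)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + ho, j : j + wo] += (
                            g * wd[None, :, i, j, None, None]
                        )
                x._accumulate(dxp[:, :, p : p + h, p : p + w] if p else dxp)
        out._backward = bwd
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on NCHW tensors (even H and W)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial size, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(3, 5))
    out = _result(out_data, (x,))
    if out.requires_grad:
        mask = (blocks == out_data[:, :, :, None, :, None]).astype(np.float64)
        mask /= mask.sum(axis=(3, 5), keepdims=True)

        def bwd(g, a=x, m=mask):
            gb = g[:, :, :, None, :, None] * m
            a._accumulate(gb.reshape(a.data.shape))
        out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling on NCHW tensors."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = _result(out_data, (x,))
    if out.requires_grad:
        n, c, h, w = x.data.shape

        def bwd(g, a=x, n=n, c=c, h=h, w=w):
            a._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
        out._backward = bwd
    return out


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm_sq = (x * x).sum(axis=axis, keepdims=True)
    return x * ((norm_sq + eps) ** -0.5)


# ---------------------------------------------------------------------------
# modules, optimizer, schedule
# ---------------------------------------------------------------------------

class Module:
    """Base class with attribute-order parameter traversal.

    Parameters are discovered by walking instance attributes (and lists or
    tuples of modules/parameters) in insertion order, which makes state
    dictionaries deterministic.
    """

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters(prefix)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, param in own.items():
            value = np.asarray(state[name], dtype=np.float64)
            if value.shape != param.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {value.shape} vs {param.data.shape}"
                )
            param.data = value.copy()


class Linear(Module):
    """Affine map y = x W + b with Lecun-style initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            rng.standard_normal((in_features, out_features)) * scale
        )
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1 ** self._t)
            v_hat = v / (1.0 - b2 ** self._t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


def cosine_annealed_lr(step: int, total_steps: int, lr_init: float, lr_min: float) -> float:
    """Cosine annealing from ``lr_init`` at step 0 to ``lr_min`` at the final step."""
    if total_steps <= 1:
        return lr_init
    t = step / (total_steps - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * t))
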