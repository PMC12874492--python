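"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each operation returns a :class:`Tensor` holding
the result plus a closure that maps the output cotangent to cotangents of
its parents.  ``Tensor.backward`` walks the tape in reverse topological
order.  Only the operations the segmentation network needs are provided;
shapes follow numpy broadcasting, with gradients "unbroadcast" (summed over
expanded axes) on the way back.

Feature maps are channels-last ``(B, H, W, C)`` throughout the package;
sequences are ``(B, L, D)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "scale",
    "exp", "log", "sigmoid", "relu", "softplus", "silu", "clip",
    "tsum", "tmean", "reshape", "transpose", "flip", "concat",
    "linear", "layer_norm", "bilinear_upsample", "nearest_upsample",
    "maxpool2x2", "causal_conv1d", "depthwise_conv2d_3x3",
]


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp: Callable | None = None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
            if not np.issubdtype(data.dtype, np.floating):
                data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._vjp = vjp

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators ------------------------------------------------------
    # python scalars go through affine/scale so they do not promote the
    # array dtype (float32 nets stay float32)
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return affine(self, 1.0, other)
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return affine(self, 1.0, -other)
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return affine(self, -1.0, other)
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, other)
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, 1.0 / other)
        return div(self, as_tensor(other))

    def __neg__(self):
        return neg(self)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    return Tensor(arr)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._vjp is not None for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, vjp) -> Tensor:
    if _needs(*parents):
        return Tensor(data, parents=tuple(parents), vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape),
                                         _unbroadcast(g, b.data.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape),
                                         _unbroadcast(-g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g * b.data, a.data.shape),
                                         _unbroadcast(g * a.data, b.data.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data
    def vjp(g):
        return (_unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
    return _make(out, (a, b), vjp)


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: (-g,))


def scale(a: Tensor, c: float) -> Tensor:
    c = float(c)
    return _make(a.data * c, (a,), lambda g: (g * c,))


def affine(a: Tensor, c: float, d: float) -> Tensor:
    """``c * a + d`` with python scalars (dtype-preserving)."""
    c, d = float(c), float(d)
    return _make(a.data * c + d, (a,), lambda g: (g * c,))


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: (g * out,))


def log(a: Tensor) -> Tensor:
    out = np.log(a.data)
    return _make(out, (a,), lambda g: (g / a.data,))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0.0)
    return _make(out, (a,), lambda g: (g * (a.data > 0),))


def softplus(a: Tensor) -> Tensor:
    # log(1+e^x), overflow-safe
    out = np.logaddexp(0.0, a.data)
    return _make(out, (a,), lambda g: (g / (1.0 + np.exp(-a.data)),))


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s
    return _make(out, (a,), lambda g: (g * (s * (1.0 + a.data * (1.0 - s))),))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)
    return _make(out, (a,), lambda g: (g * inside,))


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            for i in sorted(ax):
                g = np.expand_dims(g, i % a.data.ndim)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _make(out, (a,), vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    out = a.data.reshape(shape)
    return _make(out, (a,), lambda g: (g.reshape(a.data.shape),))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = a.data.transpose(axes)
    return _make(out, (a,), lambda g: (g.transpose(inv),))


def flip(a: Tensor, axis: int) -> Tensor:
    out = np.flip(a.data, axis=axis)
    return _make(out, (a,), lambda g: (np.flip(g, axis=axis),))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    if _needs(*tensors):
        return Tensor(out, parents=tuple(tensors), vjp=vjp)
    return Tensor(out)


# ---------------------------------------------------------------------------
# learnable layers as fused ops
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w + b`` over the last axis; x: (..., Cin), w: (Cin, Cout)."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        gx = g @ w.data.T
        gw = x.data.reshape(-1, x.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        if b is None:
            return (gx, gw)
        return (gx, gw, g.reshape(-1, g.shape[-1]).sum(axis=0))

    return _make(out, parents, vjp)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last (channel) axis per position."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def vjp(g):
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        gx = (dxhat - m1 - xhat * m2) * inv
        axes = tuple(range(g.ndim - 1))
        return (gx, (g * xhat).sum(axis=axes), g.sum(axis=axes))

    return _make(out, (x, gamma, beta), vjp)


# ---------------------------------------------------------------------------
# spatial resampling (channels-last (B, H, W, C))
# ---------------------------------------------------------------------------

def _bilinear_weights(n_in: int, n_out: int):
    """Half-pixel-centre source coordinates (align_corners=False)."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    i0 = np.floor(pos).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = pos - i0
    return i0, i1, 1.0 - w1, w1


def bilinear_upsample(x: Tensor, out_h: int, out_w: int) -> Tensor:
    B, H, W, C = x.data.shape
    y0, y1, wy0, wy1 = _bilinear_weights(H, out_h)
    x0, x1, wx0, wx1 = _bilinear_weights(W, out_w)
    wy0, wy1 = wy0.astype(x.data.dtype), wy1.astype(x.data.dtype)
    wx0, wx1 = wx0.astype(x.data.dtype), wx1.astype(x.data.dtype)
    wy0c = wy0[:, None, None]
    wy1c = wy1[:, None, None]
    wx0c = wx0[None, :, None]
    wx1c = wx1[None, :, None]
    d = x.data
    out = (d[:, y0][:, :, x0] * (wy0c * wx0c)
           + d[:, y0][:, :, x1] * (wy0c * wx1c)
           + d[:, y1][:, :, x0] * (wy1c * wx0c)
           + d[:, y1][:, :, x1] * (wy1c * wx1c))

    def vjp(g):
        gx = np.zeros_like(d)
        for yi, wy in ((y0, wy0c), (y1, wy1c)):
            for xi, wx in ((x0, wx0c), (x1, wx1c)):
                contrib = g * (wy * wx)
                np.add.at(gx, (slice(None), yi[:, None], xi[None, :]), contrib)
        return (gx,)

    return _make(out, (x,), vjp)


def nearest_upsample(x: Tensor, out_h: int, out_w: int) -> Tensor:
    B, H, W, C = x.data.shape
    yi = np.minimum((np.arange(out_h) * H // out_h), H - 1)
    xi = np.minimum((np.arange(out_w) * W // out_w), W - 1)
    out = x.data[:, yi][:, :, xi]

    def vjp(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), yi[:, None], xi[None, :]), g)
        return (gx,)

    return _make(out, (x,), vjp)


def maxpool2x2(x: Tensor) -> Tensor:
    B, H, W, C = x.data.shape
    r = x.data.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    r = r.reshape(B, H // 2, W // 2, 4, C)
    idx = r.argmax(axis=3)
    out = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def vjp(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gr = gr.reshape(B, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        return (gr.reshape(B, H, W, C),)

    return _make(out, (x,), vjp)


# ---------------------------------------------------------------------------
# depthwise convolutions via shifted adds
# ---------------------------------------------------------------------------

def causal_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise causal convolution along the sequence axis.

    x: (B, L, D), w: (K, D); out[t] = sum_k w[k] * x[t - (K-1) + k].
    """
    B, L, D = x.data.shape
    K = w.data.shape[0]
    pad = np.zeros((B, K - 1, D), dtype=x.data.dtype)
    xp = np.concatenate([pad, x.data], axis=1)
    out = np.zeros_like(x.data)
    for k in range(K):
        out += w.data[k] * xp[:, k:k + L]
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k in range(K):
            gxp[:, k:k + L] += g * w.data[k]
            gw[k] = (g * xp[:, k:k + L]).sum(axis=(0, 1))
        gx = gxp[:, K - 1:]
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 1)))

    return _make(out, parents, vjp)


def depthwise_conv2d_3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise 3x3 convolution, zero padding; x: (B,H,W,C), w: (3,3,C)."""
    B, H, W, C = x.data.shape
    xp = np.zeros((B, H + 2, W + 2, C), dtype=x.data.dtype)
    xp[:, 1:H + 1, 1:W + 1] = x.data
    out = np.zeros_like(x.data)
    for i in range(3):
        for j in range(3):
            out += w.data[i, j] * xp[:, i:i + H, j:j + W]
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(3):
            for j in range(3):
                gxp[:, i:i + H, j:j + W] += g * w.data[i, j]
                gw[i, j] = (g * xp[:, i:i + H, j:j + W]).sum(axis=(0, 1, 2))
        gx = gxp[:, 1:H + 1, 1:W + 1]
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 1, 2)))

    return _make(out, parents, vjp)


# ---------------------------------------------------------------------------
# module container
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container (walks attributes recursively)."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        missing = set(named) - set(state)
        extra = set(state) - set(named)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype) -> "Module":
        """Cast every parameter in place (e.g. float32 for training speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))
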