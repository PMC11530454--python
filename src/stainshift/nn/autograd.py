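"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations needed by the detection and embedding
networks in this package: dense/convolutional linear maps, ReLU, sigmoid,
exponentials, channel concatenation, per-position layer normalisation,
nearest-neighbour upsampling, reductions, and elementwise arithmetic.
Gradients are accumulated by a topological backward sweep, as in any
tape-based framework.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- elementwise -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data
        rg = self.requires_grad or other.requires_grad

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out = Tensor._make(data, (self, other), backward, rg)
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data
        rg = self.requires_grad or other.requires_grad

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out = Tensor._make(data, (self, other), backward, rg)
        return out

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(self.data * mask, (self,), backward, self.requires_grad)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out = Tensor._make(s, (self,), backward, self.requires_grad)
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -30, 30))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * e)

        out = Tensor._make(e, (self,), backward, self.requires_grad)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / np.maximum(self.data, 1e-12))

        out = Tensor._make(np.log(np.maximum(self.data, 1e-12)), (self,), backward,
                           self.requires_grad)
        return out

    def pow_const(self, p: float):
        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * np.power(self.data, p - 1))

        out = Tensor._make(np.power(self.data, p), (self,), backward, self.requires_grad)
        return out

    # -- reductions / reshapes ---------------------------------------------

    def sum(self):
        def backward():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad, self.data.shape))

        out = Tensor._make(self.data.sum(keepdims=False), (self,), backward,
                           self.requires_grad)
        return out

    def mean(self):
        n = self.data.size

        def backward():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad / n, self.data.shape))

        out = Tensor._make(self.data.mean(), (self,), backward, self.requires_grad)
        return out

    def reshape(self, *shape):
        old = self.data.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        out = Tensor._make(self.data.reshape(*shape), (self,), backward,
                           self.requires_grad)
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward,
                           self.requires_grad)
        return out

    def matmul(self, other: "Tensor"):
        rg = self.requires_grad or other.requires_grad
        data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out = Tensor._make(data, (self, other), backward, rg)
        return out

    def gather_rows(self, index: np.ndarray):
        """Select rows of a 2-D tensor (used to pick positive locations)."""
        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accum(g)

        out = Tensor._make(self.data[index], (self,), backward, self.requires_grad)
        return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over broadcast axes back to the target shape."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two NCHW tensors along the channel axis."""
    ca = a.data.shape[1]
    rg = a.requires_grad or b.requires_grad
    data = np.concatenate([a.data, b.data], axis=1)

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    out = Tensor._make(data, (a, b), backward, rg)
    return out


def layernorm_channels(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the channel axis, independently at each spatial position.

    ``gain`` and ``bias`` have shape (C,) and are broadcast over N, H, W.
    """
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gcol = gain.data.reshape(1, -1, 1, 1)
    data = xhat * gcol + bias.data.reshape(1, -1, 1, 1)
    rg = x.requires_grad or gain.requires_grad or bias.requires_grad
    C = x.data.shape[1]

    def backward():
        g = out.grad
        if gain.requires_grad:
            gain._accum((g * xhat).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = g * gcol  # dL/dxhat
            dx = inv * (gx - gx.mean(axis=1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=1, keepdims=True))
            x._accum(dx.astype(np.float32))

    out = Tensor._make(data, (x, gain, bias), backward, rg)
    return out


def layernorm_full(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over all of (C, H, W) per sample (the per-level alternative
    to the per-position normalisation used by the fusion blocks)."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gcol = gain.data.reshape(1, -1, 1, 1)
    data = xhat * gcol + bias.data.reshape(1, -1, 1, 1)
    rg = x.requires_grad or gain.requires_grad or bias.requires_grad
    m = x.data[0].size

    def backward():
        g = out.grad
        if gain.requires_grad:
            gain._accum((g * xhat).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = g * gcol
            dx = inv * (gx - gx.mean(axis=axes, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=axes, keepdims=True))
            x._accum(dx.astype(np.float32))

    out = Tensor._make(data, (x, gain, bias), backward, rg)
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum: min(a, b) = a - relu(a - b)."""
    return a - (a - b).relu()


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NCHW tensor."""
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward():
        if x.requires_grad:
            g = out.grad
            n, c, h, w = g.shape
            g = g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
            x._accum(g)

    out = Tensor._make(data, (x,), backward, x.requires_grad)
    return out


def crop_like(x: Tensor, h: int, w: int) -> Tensor:
    """Crop an NCHW tensor to (h, w); needed when upsampled maps overshoot."""
    if x.data.shape[2] == h and x.data.shape[3] == w:
        return x

    def backward():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[:, :, :h, :w] = out.grad
            x._accum(g)

    out = Tensor._make(x.data[:, :, :h, :w], (x,), backward, x.requires_grad)
    return out


# ---------------------------------------------------------------------------
# convolution via im2col


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, ho, wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    # (n, ho, wo, c*k*k)
    col = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k)
    return col, ho, wo


def _col2im(col: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    xg = np.zeros((n, c, hp, wp), dtype=np.float32)
    col = col.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            xg[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += col[:, :, :, :, i, j]
    if pad:
        xg = xg[:, :, pad:hp - pad, pad:wp - pad]
    return xg


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution, NCHW input, (Cout, Cin, k, k) weight."""
    co, ci, k, _ = weight.data.shape
    col, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(co, ci * k * k)
    outm = col @ wmat.T
    if bias is not None:
        outm += bias.data
    n = x.data.shape[0]
    data = outm.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    rg = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def backward():
        g = out.grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=0))
        if weight.requires_grad:
            weight._accum((g.T @ col).reshape(co, ci, k, k))
        if x.requires_grad:
            gcol = g @ wmat
            x._accum(_col2im(gcol, x.data.shape, k, stride, pad, ho, wo))

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(data, parents, backward, rg)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial axes of an NCHW tensor → (N, C)."""
    n, c, h, w = x.data.shape

    def backward():
        if x.requires_grad:
            g = out.grad.reshape(n, c, 1, 1) / (h * w)
            x._accum(np.broadcast_to(g, x.data.shape).astype(np.float32))

    out = Tensor._make(x.data.mean(axis=(2, 3)), (x,), backward, x.requires_grad)
    return out


def maxpool2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (input spatial dims must be even)."""
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    data = xr.max(axis=(3, 5))
    amax = (xr == data[:, :, :, None, :, None])

    def backward():
        if x.requires_grad:
            g = out.grad[:, :, :, None, :, None] * amax
            x._accum(g.reshape(n, c, h, w).astype(np.float32))

    out = Tensor._make(data, (x,), backward, x.requires_grad)
    return out


# ---------------------------------------------------------------------------
# parameters and optimiser


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
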