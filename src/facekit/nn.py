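"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the internal engine behind the gradient-trained models in this
package (the keypoint tracker and the behavioral encoder).  It provides a
``Tensor`` with a recorded operation tape, the handful of ops those models
need (dense and convolutional layers, pooling/upsampling, pointwise
nonlinearities and fused losses), and Adam/AdamW optimizers with decoupled
weight decay.

Everything is float64 numpy; determinism is guaranteed by passing explicit
``numpy.random.Generator`` objects to the initializers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(float)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic ops ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Row-subset along axis 0 (e.g. subsampling features at neural frames)."""
        out = Tensor(self.data[idx])
        out._parents = (self,)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Convolutions, pooling, upsampling  (NCHW layout)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution: x (B,C,H,W), w (O,C,kh,kw).

    Implemented as a sum of shifted channel contractions (one BLAS call per
    kernel tap), which beats explicit im2col for the small kernels used here.
    """
    B, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = np.zeros((B, H, W, O), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            y += np.tensordot(xp[:, :, i : i + H, j : j + W], w.data[:, :, i, j],
                              axes=([1], [1]))
    y = y.transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    out = Tensor(y)
    out._parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + H, j : j + W]
                gw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, i : i + H, j : j + W] += np.tensordot(
                    g, w.data[:, :, i, j], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(gxp[:, :, ph : ph + H, pw : pw + W])

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (H, W must be even)."""
    B, C, H, W = x.data.shape
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    arg = r.argmax(axis=-1)
    out = Tensor(np.take_along_axis(r, arg[..., None], axis=-1)[..., 0])
    out._parents = (x,)

    def bwd(g):
        gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(B, C, H, W))

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    B, C, H, W = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3))
    out._parents = (x,)

    def bwd(g):
        gr = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
        x._accumulate(gr)

    out._backward = bwd
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1))
    out._parents = (a, b)

    def bwd(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    out._backward = bwd
    return out


def conv1d_temporal(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Centered zero-padded temporal convolution.

    x is (T, C_in), w is (C_out, C_in, L) with odd L; output (T, C_out).
    Full cross-channel mixing (each output filter sees all input channels).
    """
    T, C = x.data.shape
    O, _, L = w.data.shape
    p = L // 2
    xp = np.pad(x.data, ((p, p), (0, 0)))
    win = sliding_window_view(xp, L, axis=0)  # T, C, L
    cols = win.reshape(T, C * L)
    wmat = w.data.reshape(O, C * L)
    y = cols @ wmat.T
    if b is not None:
        y = y + b.data
    out = Tensor(y)
    out._parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        w._accumulate((g.T @ cols).reshape(O, C, L))
        if b is not None:
            b._accumulate(g.sum(axis=0))
        gcols = (g @ wmat).reshape(T, C, L)
        gxp = np.zeros((T + 2 * p, C))
        for j in range(L):
            gxp[j : j + T] += gcols[:, :, j]
        x._accumulate(gxp[p : p + T])

    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, in) @ w (in, out) + b."""
    out = x.matmul(w)
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# Fused losses
# ---------------------------------------------------------------------------


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out = Tensor(np.mean(diff**2))
    out._parents = (pred,)
    out._backward = lambda g: pred._accumulate(g * 2.0 * diff / diff.size)
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy over unmasked elements; sigmoid fused for stability."""
    z, t = logits.data, target
    m = np.ones_like(z) if mask is None else np.asarray(mask, dtype=z.dtype)
    n = max(m.sum(), 1.0)
    # log(1+exp(z)) computed stably
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) * m
    out = Tensor(loss.sum() / n)
    out._parents = (logits,)
    sig = 1.0 / (1.0 + np.exp(-z))
    out._backward = lambda g: logits._accumulate(g * (sig - t) * m / n)
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None, beta: float = 1.0) -> Tensor:
    d = pred.data - target
    m = np.ones_like(d) if mask is None else np.asarray(mask, dtype=d.dtype)
    n = max(m.sum(), 1.0)
    absd = np.abs(d)
    loss = np.where(absd < beta, 0.5 * d**2 / beta, absd - 0.5 * beta) * m
    out = Tensor(loss.sum() / n)
    out._parents = (pred,)
    grad = np.where(absd < beta, d / beta, np.sign(d)) * m / n
    out._backward = lambda g: pred._accumulate(g * grad)
    return out


def add_scaled(a: Tensor, b: Tensor, s: float) -> Tensor:
    out = Tensor(a.data + s * b.data)
    out._parents = (a, b)

    def bwd(g):
        a._accumulate(g)
        b._accumulate(g * s)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s)
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g * s * (1 - s))
    return out


# ---------------------------------------------------------------------------
# Parameters and optimizers
# ---------------------------------------------------------------------------


def parameter(rng: np.random.Generator, shape, fan_in: int | None = None,
              dtype=np.float64) -> Tensor:
    """He-initialized weight tensor."""
    if fan_in is None:
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape).astype(dtype), requires_grad=True)


def zeros_parameter(shape, dtype=np.float64) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


class Adam:
    """Adam with optional decoupled weight decay (AdamW when ``decoupled=True``)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, decoupled=False):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def AdamW(params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
    return Adam(params, lr=lr, betas=betas, eps=eps, weight_decay=weight_decay, decoupled=True)
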