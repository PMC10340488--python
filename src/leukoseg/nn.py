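"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations a small encoder–decoder segmentation network
needs: broadcast-aware arithmetic, matmul-based 2-D convolution (im2col),
instance normalization, Mish/sigmoid nonlinearities, nearest-neighbor
upsampling, channel concatenation, inverted dropout, and reductions — plus an
Adam optimizer.  Gradients are exact (verified against central finite
differences in the test suite); everything is float64 for numerical
robustness at the small problem sizes this package targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))
        out._backward = lambda g: (self._accum(_unbroadcast(g, self.shape)),
                                   other._accum(_unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, True, (self, other))
        out._backward = lambda g: (self._accum(_unbroadcast(g * other.data, self.shape)),
                                   other._accum(_unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def pow_const(self, e: float):
        """self ** e for a constant exponent."""
        out = Tensor(self.data ** e, True, (self,))
        out._backward = lambda g: self._accum(g * e * self.data ** (e - 1.0))
        return out

    # -- elementwise functions ---------------------------------------------

    def log(self):
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip_min(self, lo: float):
        """max(self, lo); gradient passes only where self > lo."""
        out = Tensor(np.maximum(self.data, lo), True, (self,))
        out._backward = lambda g: self._accum(g * (self.data > lo))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, True, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def mish(self):
        """x * tanh(softplus(x)), the Mish activation."""
        x = self.data
        sp = np.logaddexp(0.0, x)          # softplus, stable for |x| large
        t = np.tanh(sp)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        out = Tensor(x * t, True, (self,))
        # d/dx = tanh(sp) + x * sech^2(sp) * sigmoid(x)
        out._backward = lambda g: self._accum(g * (t + x * (1.0 - t ** 2) * sig))
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structured ops ---------------------------------------------------------


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N, C, H, W) tensors along the channel axis."""
    ca = a.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), True, (a, b))
    out._backward = lambda g: (a._accum(g[:, :ca]), b._accum(g[:, ca:]))
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling of an (N, C, H, W) tensor."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), True, (x,))
    n, c, h, w = x.shape
    out._backward = lambda g: x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, True, (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,).  Output spatial size is
    floor((H + 2p - kh) / stride) + 1.
    """
    n, c, _, _ = x.shape
    f, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(f, -1)
    out_data = (cols @ wmat.T + b.data).reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    out = Tensor(out_data, True, (x, w, b))

    def bw(g):
        dmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        w._accum((dmat.T @ cols).reshape(w.shape))
        b._accum(g.sum(axis=(0, 2, 3)))
        dcols = (dmat @ wmat).reshape(n, ho, wo, c, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)
    out._backward = bw
    return out


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance normalization over each (sample, channel) spatial plane.

    gain and bias have shape (1, C, 1, 1).
    """
    mu = x.mean(axis=(2, 3), keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=(2, 3), keepdims=True)
    inv = (var + eps).pow_const(-0.5)
    return centered * inv * gain + bias


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 10, min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
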