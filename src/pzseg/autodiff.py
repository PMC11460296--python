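"""Minimal reverse-mode autodiff core for the segmentation networks.

A deliberately small tensor engine: just the operations the dual-decoder
encoder--decoder family needs (stride-1 same-padded N-D convolution, batch
normalisation, activations, 2x in-plane max-pooling/up-sampling, channel
concatenation, spatial dropout, sigmoid) plus an Adam optimiser.  Data layout
is channels-first: ``(N, C, H, W)`` in 2D and ``(N, C, H, W, D)`` in 3D.

Gradients flow through a tape of :class:`Tensor` nodes; ``backward`` seeds one
or more output tensors (the two decoder heads) and accumulates into every
parameter's ``grad``.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "backward", "conv_nd", "batch_norm", "activation",
           "sigmoid", "max_pool", "upsample", "concat", "add",
           "spatial_dropout", "Adam"]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False,
                 name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.parents: Tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None


def _topo(outputs: Sequence[Tensor]) -> List[Tensor]:
    seen, order = set(), []
    stack = [(o, False) for o in outputs]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def backward(outputs: Sequence[Tensor], seed_grads: Sequence[np.ndarray]) -> None:
    """Accumulate d(sum of seeded scalars)/d(param) for every reachable param."""
    order = _topo(outputs)
    for o, g in zip(outputs, seed_grads):
        o.grad = np.asarray(g, dtype=np.float64) if o.grad is None else o.grad + g
    for node in reversed(order):
        if node.grad is None or node._backward is None:
            continue
        node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# convolution

def _pad_same(x: np.ndarray, kernel) -> np.ndarray:
    pads = [(0, 0), (0, 0)] + [((k - 1) // 2, (k - 1) // 2) for k in kernel]
    return np.pad(x, pads)


def _conv_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padded cross-correlation. x: (N,C,*S), w: (F,C,*K)."""
    kernel = w.shape[2:]
    xp = _pad_same(x, kernel)
    nd = len(kernel)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
    if nd == 2:
        return np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)
    return np.einsum("nchwdijk,fcijk->nfhwd", win, w, optimize=True)


def conv_nd(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Zero-padded stride-1 convolution with bias; spatial shape preserved."""
    kernel = w.shape[2:]
    nd = len(kernel)
    y = _conv_forward(x.data, w.data)
    y += b.data.reshape((1, -1) + (1,) * nd)
    out = Tensor(y, parents=(x, w, b))

    def _bw(gy: np.ndarray):
        _accum(b, gy.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        xp = _pad_same(x.data, kernel)
        win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
        if nd == 2:
            _accum(w, np.einsum("nfhw,nchwij->fcij", gy, win, optimize=True))
        else:
            _accum(w, np.einsum("nfhwd,nchwdijk->fcijk", gy, win, optimize=True))
        if x.requires_grad:
            wf = np.flip(w.data, axis=tuple(range(2, 2 + nd)))
            gp = _pad_same(gy, kernel)
            gwin = sliding_window_view(gp, kernel, axis=tuple(range(2, 2 + nd)))
            if nd == 2:
                gx = np.einsum("nfhwij,fcij->nchw", gwin, wf, optimize=True)
            else:
                gx = np.einsum("nfhwdijk,fcijk->nchwd", gwin, wf, optimize=True)
            _accum(x, gx)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# batch normalisation

class BatchNormState:
    """Running statistics for one batch-norm layer (eval mode)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, state: BatchNormState,
               training: bool) -> Tensor:
    nd = x.data.ndim - 2
    axes = (0,) + tuple(range(2, 2 + nd))
    bshape = (1, -1) + (1,) * nd
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        state.mean = (1 - state.momentum) * state.mean + state.momentum * mu
        state.var = (1 - state.momentum) * state.var + state.momentum * var
    else:
        mu, var = state.mean, state.var
    inv = 1.0 / np.sqrt(var + state.eps)
    xhat = (x.data - mu.reshape(bshape)) * inv.reshape(bshape)
    y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    out = Tensor(y, parents=(x, gamma, beta))

    def _bw(gy: np.ndarray):
        _accum(gamma, (gy * xhat).sum(axis=axes))
        _accum(beta, gy.sum(axis=axes))
        if x.requires_grad:
            g = gy * gamma.data.reshape(bshape)
            if training:
                m = np.prod([x.data.shape[a] for a in axes])
                gm = g.mean(axis=axes).reshape(bshape)
                gxh = (g * xhat).mean(axis=axes).reshape(bshape)
                gx = inv.reshape(bshape) * (g - gm - xhat * gxh)
            else:
                gx = g * inv.reshape(bshape)
            _accum(x, gx)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# activations

def activation(x: Tensor, kind: str) -> Tensor:
    if kind == "relu":
        y = np.maximum(x.data, 0.0)
        dydx = (x.data > 0).astype(np.float64)
    elif kind == "leaky_relu":
        y = np.where(x.data > 0, x.data, 0.01 * x.data)
        dydx = np.where(x.data > 0, 1.0, 0.01)
    elif kind == "elu":
        e = np.exp(np.minimum(x.data, 0.0))
        y = np.where(x.data > 0, x.data, e - 1.0)
        dydx = np.where(x.data > 0, 1.0, e)
    else:
        raise ValueError(f"unknown activation {kind!r}")
    out = Tensor(y, parents=(x,))
    out._backward = lambda gy: _accum(x, gy * dydx)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(y, parents=(x,))
    out._backward = lambda gy: _accum(x, gy * y * (1.0 - y))
    return out


# ---------------------------------------------------------------------------
# pooling / upsampling (2x2 in-plane; the through-plane axis is never pooled)

def max_pool(x: Tensor) -> Tensor:
    """2x2 max-pool over (H, W); 3D inputs keep their depth axis."""
    d = x.data
    nd = d.ndim - 2
    n, c, h, w = d.shape[:4]
    if h % 2 or w % 2:
        raise ValueError(f"in-plane shape ({h},{w}) not divisible by 2")
    if nd == 2:
        blocks = d.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    else:
        dep = d.shape[4]
        blocks = d.reshape(n, c, h // 2, 2, w // 2, 2, dep).transpose(0, 1, 2, 4, 6, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, dep, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def _bw(gy: np.ndarray):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], gy[..., None], axis=-1)
        if nd == 2:
            gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            gx = gx.reshape(n, c, h, w)
        else:
            dep = d.shape[4]
            gx = gflat.reshape(n, c, h // 2, w // 2, dep, 2, 2)
            gx = gx.transpose(0, 1, 2, 5, 3, 6, 4).reshape(n, c, h, w, dep)
        _accum(x, gx)

    out._backward = _bw
    return out


def upsample(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x up-sampling over (H, W)."""
    nd = x.data.ndim - 2
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, parents=(x,))

    def _bw(gy: np.ndarray):
        n, c = gy.shape[:2]
        h2, w2 = gy.shape[2] // 2, gy.shape[3] // 2
        if nd == 2:
            gx = gy.reshape(n, c, h2, 2, w2, 2).sum(axis=(3, 5))
        else:
            dep = gy.shape[4]
            gx = gy.reshape(n, c, h2, 2, w2, 2, dep).sum(axis=(3, 5))
        _accum(x, gx)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# structure ops

def concat(xs: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    y = np.concatenate([t.data for t in xs], axis=1)
    out = Tensor(y, parents=tuple(xs))
    sizes = [t.data.shape[1] for t in xs]

    def _bw(gy: np.ndarray):
        start = 0
        for t, s in zip(xs, sizes):
            _accum(t, gy[:, start:start + s])
            start += s

    out._backward = _bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(gy: np.ndarray):
        _accum(a, gy)
        _accum(b, gy)

    out._backward = _bw
    return out


def spatial_dropout(x: Tensor, p: float, rng: np.random.Generator,
                    training: bool) -> Tensor:
    """Channel-wise dropout: whole feature maps are zeroed with probability p."""
    if not training or p <= 0.0:
        return x
    nd = x.data.ndim - 2
    keep = (rng.random((x.data.shape[0], x.data.shape[1])) >= p).astype(np.float64)
    mask = keep.reshape(keep.shape + (1,) * nd) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda gy: _accum(x, gy * mask)
    return out


# ---------------------------------------------------------------------------
# optimiser

class Adam:
    """Adaptive-moment optimiser over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
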