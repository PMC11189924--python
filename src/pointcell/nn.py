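"""Minimal reverse-mode autodiff on numpy arrays, sized for this model.

Implements exactly the differentiable operations the segmentation network
needs — 2-D convolution, 2x2-stride-2 transposed convolution, linear
layers, ReLU, nearest x2 upsampling, bilinear grid gathering, RoI align —
plus stabilized binary-cross-entropy / smooth-L1 losses and SGD with
momentum. Single-image layout: feature tensors are ``(C, H, W)``; batching
is gradient accumulation across images.
"""

from __future__ import annotations

import numpy as np

from .sampling import Box, bilinear_weights, roi_sample_points

__all__ = [
    "Tensor",
    "tensor",
    "relu",
    "add",
    "conv2d",
    "conv_transpose2x",
    "linear",
    "upsample2x_nearest",
    "grid_gather",
    "roi_align_t",
    "concat_cols",
    "sigmoid",
    "bce_with_logits",
    "smooth_l1",
    "Conv2d",
    "ConvT2x2",
    "Linear",
    "SGD",
    "kaiming",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __add__(self, other):
        return add(self, other)

    def item(self) -> float:
        return float(self.data)


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out._backward = back
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = back
    return out


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return w[:, ::s, ::s]  # (C, Ho, Wo, k, k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; ``x`` is (Cin,H,W), ``weight`` (Cout,Cin,k,k)."""
    k = weight.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = _windows(xp, k, stride)
    out_data = np.einsum("cijab,ocab->oij", win, weight.data, optimize=True)
    out_data += bias.data[:, None, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def back(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("cijab,oij->ocab", win, g, optimize=True))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))
        if x.requires_grad:
            contrib = np.einsum("ocab,oij->cijab", weight.data, g, optimize=True)
            gxp = np.zeros_like(xp)
            ho, wo = g.shape[1], g.shape[2]
            for a in range(k):
                for b in range(k):
                    gxp[:, a : a + stride * ho : stride, b : b + stride * wo : stride] += contrib[:, :, :, a, b]
            gx = gxp[:, pad : gxp.shape[1] - pad, pad : gxp.shape[2] - pad] if pad else gxp
            x._accumulate(gx)

    out._backward = back
    return out


def conv_transpose2x(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: exact spatial doubling.

    ``x`` is (Cin,H,W); ``weight`` (Cin,Cout,2,2); output (Cout,2H,2W).
    """
    cin, h, w = x.data.shape
    cout = weight.data.shape[1]
    t = np.einsum("chw,coab->ohawb", x.data, weight.data, optimize=True)
    out_data = t.reshape(cout, 2 * h, 2 * w) + bias.data[:, None, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def back(g):
        g5 = g.reshape(cout, h, 2, w, 2)  # (o, h, a, w, b)
        if weight.requires_grad:
            weight._accumulate(np.einsum("ohawb,chw->coab", g5, x.data, optimize=True))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))
        if x.requires_grad:
            x._accumulate(np.einsum("ohawb,coab->chw", g5, weight.data, optimize=True))

    out._backward = back
    return out


def upsample2x_nearest(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Tensor(out_data, parents=(x,))

    def back(g):
        if x.requires_grad:
            c, h2, w2 = g.shape
            x._accumulate(g.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4)))

    out._backward = back
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """``x`` (N,Cin) @ ``weight`` (Cin,Cout) + bias."""
    out = Tensor(x.data @ weight.data + bias.data, parents=(x, weight, bias))

    def back(g):
        if weight.requires_grad:
            weight._accumulate(x.data.T @ g)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ weight.data.T)

    out._backward = back
    return out


def grid_gather(x: Tensor, rows: np.ndarray, cols: np.ndarray, wts: np.ndarray) -> Tensor:
    """Differentiable bilinear gather: (C,H,W) sampled at N stencils -> (N,C)."""
    v = x.data[:, rows, cols]  # (C, N, 4)
    out = Tensor(np.einsum("cnk,nk->nc", v, wts, optimize=True), parents=(x,))
    c, h, w = x.data.shape

    def back(g):
        if x.requires_grad:
            gx = np.zeros((c, h * w))
            flat = rows * w + cols  # (N, 4)
            contrib = g.T[:, :, None] * wts[None, :, :]  # (C, N, 4)
            np.add.at(gx, (np.arange(c)[:, None, None], flat[None, :, :]), contrib)
            x._accumulate(gx.reshape(c, h, w))

    out._backward = back
    return out


def sample_points_t(x: Tensor, xs: np.ndarray, ys: np.ndarray, stride: float) -> Tensor:
    """Differentiable bilinear sampling of (C,H,W) at absolute image coords."""
    rows, cols, wts = bilinear_weights(x.data.shape[1:], xs, ys, stride)
    return grid_gather(x, rows, cols, wts)


def roi_align_t(x: Tensor, box: Box, stride: float, out_size: int = 7, sampling_ratio: int = 2) -> Tensor:
    """Differentiable RoI align of a (C,H,W) feature map -> (C,out,out)."""
    pts = roi_sample_points(box, out_size, sampling_ratio).reshape(-1, 2)
    g = grid_gather(x, *bilinear_weights(x.data.shape[1:], pts[:, 0], pts[:, 1], stride))
    r2 = sampling_ratio**2
    c = x.data.shape[0]
    out_data = g.data.reshape(out_size, out_size, r2, c).mean(axis=2)
    out_data = np.moveaxis(out_data, -1, 0)  # (C, out, out)
    out = Tensor(out_data, parents=(g,))

    def back(grad):
        if g.requires_grad:
            gg = np.moveaxis(grad, 0, -1)[:, :, None, :] / r2  # (out,out,1,C)
            g._accumulate(np.broadcast_to(gg, (out_size, out_size, r2, c)).reshape(-1, c))

    out._backward = back
    return out


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate (N,Ca) and (N,Cb) feature columns -> (N, Ca+Cb)."""
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))
    ca = a.data.shape[1]

    def back(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    out._backward = back
    return out


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy in the stabilized log-sum-exp form."""
    y = np.asarray(targets, dtype=np.float64)
    if y.shape != logits.data.shape:
        raise ValueError("targets must match logits shape")
    if y.size and not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0 or 1")
    x = logits.data
    loss = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    n = max(x.size, 1)
    out = Tensor(loss.sum() / n, parents=(logits,))

    def back(g):
        if logits.requires_grad:
            logits._accumulate(g * (sigmoid(x) - y) / n)

    out._backward = back
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    d = pred.data - np.asarray(target, dtype=np.float64)
    absd = np.abs(d)
    loss = np.where(absd < beta, 0.5 * d**2 / beta, absd - 0.5 * beta)
    n = max(d.size, 1)
    out = Tensor(loss.sum() / n, parents=(pred,))

    def back(g):
        if pred.requires_grad:
            pred._accumulate(g * np.clip(d / beta, -1.0, 1.0) / n)

    out._backward = back
    return out


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0, rng=None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(kaiming(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)

    def params(self):
        return [self.weight, self.bias]


class ConvT2x2:
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng()
        self.weight = Tensor(kaiming(rng, (cin, cout, 2, 2), cin * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x(x, self.weight, self.bias)

    def params(self):
        return [self.weight, self.bias]


class Linear:
    def __init__(self, cin: int, cout: int, rng=None, zero_init: bool = False):
        rng = rng or np.random.default_rng()
        w = np.zeros((cin, cout)) if zero_init else kaiming(rng, (cin, cout), cin)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)

    def params(self):
        return [self.weight, self.bias]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 0.002, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
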