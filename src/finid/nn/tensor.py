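"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine: just the operations the
detection and classification networks need (convolution, batch
normalisation, pooling, element-wise activations, concatenation,
nearest-neighbour upsampling and the usual losses). Everything is
float32 and fully deterministic, which is what makes seeded CPU
training reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul_scalar",
    "relu",
    "leaky_relu",
    "sigmoid",
    "conv2d",
    "batchnorm2d",
    "max_pool2x2",
    "global_avg_pool",
    "linear",
    "upsample2x",
    "concat_channels",
    "softmax_cross_entropy",
    "bce_with_logits",
    "mse",
    "sum_losses",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _node(data, parents, backward, requires_grad=None):
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=requires_grad,
                 _prev=tuple(parents) if requires_grad else ())
    if requires_grad:
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accum(g)
        b._accum(g)
    return _node(a.data + b.data, [a, b], backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def backward(g):
        a._accum(g * s)
    return _node(a.data * s, [a], backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)
    return _node(x.data * mask, [x], backward)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * np.where(mask, 1.0, slope).astype(np.float32))
    return _node(np.where(mask, x.data, x.data * slope), [x], backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * s * (1.0 - s))
    return _node(s, [x], backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel.

    Implemented as a sum of per-offset channel contractions (one einsum
    per kernel tap); for the 1x1/3x3/9x9 kernels used here this is the
    fastest pure-numpy formulation and the backward pass mirrors it.
    """
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    assert cin == cin2, f"channel mismatch {cin} vs {cin2}"
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    out = np.zeros((n, cout, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out += np.einsum("oc,nchw->nohw", w.data[:, :, i, j], xs,
                             optimize=True)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i, i + stride * ho, stride),
                      slice(j, j + stride * wo, stride))
                if dw is not None:
                    dw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, xp[sl],
                                               optimize=True)
                if x.requires_grad:
                    dxp[sl] += np.einsum("oc,nohw->nchw", w.data[:, :, i, j],
                                         g, optimize=True)
        if dw is not None:
            w._accum(dw)
        if x.requires_grad:
            if padding:
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wd])
            else:
                x._accum(dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
    parents = [x, w] if b is None else [x, w, b]
    return _node(out, parents, backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                running_var, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W); updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gxh = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                t1 = gxh.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
                t2 = np.einsum("nchw,nchw->c", gxh, xhat,
                               optimize=True).reshape(1, -1, 1, 1)
                dx = (inv.reshape(1, -1, 1, 1) / m) * (m * gxh - t1 - xhat * t2)
            else:
                dx = gxh * inv.reshape(1, -1, 1, 1)
            x._accum(dx.astype(np.float32))
    return _node(out, [x, gamma, beta], backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "max_pool2x2 needs even dims"
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    # break ties deterministically: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = ((flat & first).reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5))

    def backward(g):
        gx = mask * g[:, :, :, None, :, None]
        x._accum(gx.reshape(n, c, h, w).astype(np.float32))
    return _node(out, [x], backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (h * w),
                                 x.data.shape).astype(np.float32))
    return _node(out, [x], backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    out = x.data @ w.data.T + b.data

    def backward(g):
        if w.requires_grad:
            w._accum(g.T @ x.data)
        if b.requires_grad:
            b._accum(g.sum(axis=0))
        if x.requires_grad:
            x._accum(g @ w.data)
    return _node(out, [x, w, b], backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accum(gr.astype(np.float32))
    return _node(out, [x], backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])
    return _node(out, [a, b], backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch; labels are integer class ids."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()

    def backward(g):
        dz = p.copy()
        dz[np.arange(n), labels] -= 1.0
        logits._accum((g * dz / n).astype(np.float32))
    return _node(np.float32(loss), [logits], backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Sum of element-wise binary cross-entropy, optionally masked."""
    z = logits.data
    s = 1.0 / (1.0 + np.exp(-z))
    per = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        per = per * weights
    loss = per.sum()

    def backward(g):
        d = (s - targets)
        if weights is not None:
            d = d * weights
        logits._accum((g * d).astype(np.float32))
    return _node(np.float32(loss), [logits], backward)


def mse(pred: Tensor, targets: np.ndarray,
        weights: np.ndarray | None = None) -> Tensor:
    """Sum of squared error, optionally masked."""
    diff = pred.data - targets
    if weights is not None:
        diff = diff * np.sqrt(weights)
    loss = (diff * diff).sum()

    def backward(g):
        d = 2.0 * (pred.data - targets)
        if weights is not None:
            d = d * weights
        pred._accum((g * d).astype(np.float32))
    return _node(np.float32(loss), [pred], backward)


def sum_losses(losses: list[Tensor]) -> Tensor:
    total = np.float32(sum(float(t.data) for t in losses))

    def backward(g):
        for t in losses:
            t._accum(np.asarray(g, dtype=np.float32))
    return _node(total, losses, backward)
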