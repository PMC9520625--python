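"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the vision-transformer classifier
needs: broadcasting arithmetic, batched matmul, reshape/transpose/
concatenate, 2-D convolution (dense via im2col and depthwise), batch
and layer normalisation, SiLU, softmax, mean-reduction, and a fused
softmax cross-entropy loss.  Gradients are accumulated by topological
sort from the loss tensor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "scale", "matmul", "reshape", "transpose",
    "concat", "silu", "softmax", "mean_axes", "conv2d", "depthwise_conv2d",
    "batchnorm", "layernorm", "cross_entropy",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _node(data, parents, backward, requires_grad=True) -> Tensor:
    out = Tensor(data, requires_grad=requires_grad)
    needed = tuple(p for p in parents if p.requires_grad or p._prev)
    if needed:
        out._prev = needed
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))
    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(-g, b.shape))
    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))
    return _node(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a.accumulate(g * c)
    return _node(a.data * c, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a.accumulate(_unbroadcast(ga, a.shape))
        b.accumulate(_unbroadcast(gb, b.shape))
    return _node(np.matmul(a.data, b.data), (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        a.accumulate(g.reshape(old))
    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inverse = np.argsort(axes)

    def backward(g):
        a.accumulate(g.transpose(inverse))
    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    needed = tuple(t for t in tensors if t.requires_grad or t._prev)
    if needed:
        out._prev = needed
        out._backward = backward
    return out


def silu(a: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * sig

    def backward(g):
        a.accumulate(g * (sig * (1.0 + a.data * (1.0 - sig))))
    return _node(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a.accumulate(s * (g - dot))
    return _node(s, (a,), backward)


def mean_axes(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    count = int(np.prod([a.shape[ax] for ax in axes]))
    out_data = a.data.mean(axis=axes)

    def backward(g):
        ge = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(ge, a.shape) / count)
    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution (NHWC layout)

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Dense 2-D convolution; x is (N,H,W,Cin), w is (kh,kw,Cin,Cout)."""
    kh, kw, cin, cout = w.shape
    xp = _pad_hw(x.data, padding)
    N, Hp, Wp, _ = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    cols = np.empty((N, Ho, Wo, kh, kw, cin), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i:i + stride * Ho:stride,
                                        j:j + stride * Wo:stride, :]
    cols2 = cols.reshape(N * Ho * Wo, kh * kw * cin)
    wm = w.data.reshape(kh * kw * cin, cout)
    out_data = (cols2 @ wm).reshape(N, Ho, Wo, cout)
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        g2 = g.reshape(N * Ho * Wo, cout)
        w.accumulate((cols2.T @ g2).reshape(w.shape))
        if b is not None:
            b.accumulate(g.sum(axis=(0, 1, 2)))
        gcols = (g2 @ wm.T).reshape(N, Ho, Wo, kh, kw, cin)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i:i + stride * Ho:stride,
                    j:j + stride * Wo:stride, :] += gcols[:, :, :, i, j, :]
        gx = gxp[:, padding:gxp.shape[1] - padding,
                 padding:gxp.shape[2] - padding, :] if padding else gxp
        x.accumulate(gx)
    parents = (x, w, b) if b is not None else (x, w)
    return _node(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Per-channel convolution; w is (kh, kw, C)."""
    kh, kw, c = w.shape
    xp = _pad_hw(x.data, padding)
    N, Hp, Wp, _ = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    out_data = np.zeros((N, Ho, Wo, c), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, i:i + stride * Ho:stride,
                           j:j + stride * Wo:stride, :] * w.data[i, j]
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + stride * Ho:stride,
                           j:j + stride * Wo:stride, :]
                gw[i, j] = (g * patch).sum(axis=(0, 1, 2))
                gxp[:, i:i + stride * Ho:stride,
                    j:j + stride * Wo:stride, :] += g * w.data[i, j]
        w.accumulate(gw)
        if b is not None:
            b.accumulate(g.sum(axis=(0, 1, 2)))
        gx = gxp[:, padding:gxp.shape[1] - padding,
                 padding:gxp.shape[2] - padding, :] if padding else gxp
        x.accumulate(gx)
    parents = (x, w, b) if b is not None else (x, w)
    return _node(out_data, parents, backward)


# ---------------------------------------------------------------------------
# normalisation

def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool, momentum: float = 0.1,
              eps: float = 1e-5) -> Tensor:
    """Batch normalisation over all axes but the last (channel) axis.

    ``running_mean``/``running_var`` are updated in place in training
    mode and used directly in eval mode.
    """
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        if training:
            gm = g.mean(axis=axes)
            gx_hat = (g * xhat).mean(axis=axes)
            x.accumulate(gamma.data * inv * (g - gm - xhat * gx_hat))
        else:
            x.accumulate(g * gamma.data * inv)
    return _node(out_data, (x, gamma, beta), backward)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv

    def backward(g):
        red = tuple(range(x.data.ndim - 1))
        gamma.accumulate((g * xhat).sum(axis=red))
        beta.accumulate(g.sum(axis=red))
        gg = g * gamma.data
        gm = gg.mean(axis=-1, keepdims=True)
        gx_hat = (gg * xhat).mean(axis=-1, keepdims=True)
        x.accumulate(inv * (gg - gm - xhat * gx_hat))
    return _node(gamma.data * xhat + beta.data, (x, gamma, beta), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits.accumulate(g * grad / n)
    return _node(np.asarray(loss), (logits,), backward)
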