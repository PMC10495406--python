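"""Compact reverse-mode automatic differentiation on numpy arrays.

This is the package's training engine: a dynamically built computation graph
over dense numpy tensors, with the handful of operations the regressor needs
(broadcasted arithmetic, matmul with batched dims, im2col convolution,
activations, softmax/cross-entropy, reductions, reshaping). Gradients are
accumulated in float arrays of the same dtype as the forward data, and every
operation is covered by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph machinery --------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operators ---------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents))
    if req:
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data**p

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def log1p(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log1p(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (1.0 + a.data))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def swish(a) -> Tensor:
    """x * sigmoid(x): smooth, non-saturating for x > 0, no dead units."""
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accum(g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stabilized; used to keep loss weights > 0."""
    a = _as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (1.0 + np.exp(-a.data)))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(ts, parts):
            if t.requires_grad:
                t._accum(gp)

    return _make(out_data, tuple(ts), backward)


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

    return _make(s, (a,), backward)


def cross_entropy(logits, target_probs) -> Tensor:
    """Mean cross-entropy between rows of softmax(logits) and target rows."""
    logits = _as_tensor(logits)
    t = np.asarray(target_probs.data if isinstance(target_probs, Tensor)
                   else target_probs)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = logits.data.shape[0]
    out_data = -(t * logp).sum() / n

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accum(g * (p * t.sum(axis=-1, keepdims=True) - t) / n)

    return _make(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# Convolution (im2col / col2im through pure BLAS matmuls)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, hh, ww = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, kh, kw), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw), ho, wo


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution: x (N,C,H,W), w (F,C,kh,kw), optional bias (F,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    f, c, kh, kw = w.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(f, c * kh * kw)
    out = cols @ wmat.T                             # (N*ho*wo, F)
    out_data = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)
    out_data = np.ascontiguousarray(out_data)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, f)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # transposed convolution of g with w, via im2col again
            hi, wi = x.data.shape[2], x.data.shape[3]
            gu = np.zeros((n, f, (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                          dtype=g.dtype)
            gu[:, :, ::stride, ::stride] = g
            pq_h = kh - 1 - pad
            pq_w = kw - 1 - pad
            gup = np.pad(gu, ((0, 0), (0, 0), (pq_h, pq_h), (pq_w, pq_w)))
            # crop/pad so the output matches the input spatial size exactly
            need_h = hi + kh - 1
            need_w = wi + kw - 1
            gup = gup[:, :, :need_h, :need_w]
            if gup.shape[2] < need_h or gup.shape[3] < need_w:
                gup = np.pad(gup, ((0, 0), (0, 0),
                                   (0, need_h - gup.shape[2]),
                                   (0, need_w - gup.shape[3])))
            gcols, gh, gw = _im2col(gup, kh, kw, 1, 0)
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            wfm = np.ascontiguousarray(wflip).reshape(c, f * kh * kw)
            dx = (gcols @ wfm.T).reshape(n, gh, gw, c).transpose(0, 3, 1, 2)
            x._accum(np.ascontiguousarray(dx))

    return _make(out_data, parents, backward)


def global_avg_pool(x) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    x = _as_tensor(x)
    hw = x.data.shape[2] * x.data.shape[3]
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / hw,
                                     x.data.shape).copy())

    return _make(out_data, (x,), backward)
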