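"""Reverse-mode automatic differentiation over numpy arrays.

A minimal define-by-run engine used by the generator/critic networks. Every
primitive's vector-Jacobian product is itself built from primitives, so the
backward pass constructs a differentiable graph and second-order gradients
(required by the Wasserstein gradient penalty) come out of the same machinery.

Only the operations the networks need are implemented: elementwise arithmetic,
matmul (with numpy broadcasting), reductions, shape ops, im2col/col2im for
convolutions, and a handful of nonlinearities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "grad",
    "concat",
    "pad2d",
    "crop2d",
    "unfold",
    "fold",
    "narrow",
    "softmax",
    "leaky_relu",
]


class Tensor:
    """Array node in the computation graph.

    Wraps a float64 ndarray. Non-leaf tensors carry their parents and a
    closure computing the cotangents of those parents.
    """

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._vjp = _vjp

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return mul(self, pow_const(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_const(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return pow_const(self, float(c))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape``."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _sum_to(g, a.shape), _sum_to(g, b.shape)

    return Tensor(a.data + b.data, _parents=(a, b), _vjp=vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)

    return Tensor(a.data * b.data, _parents=(a, b), _vjp=vjp)


def neg(a: Tensor) -> Tensor:
    def vjp(g):
        return (neg(g),)

    return Tensor(-a.data, _parents=(a,), _vjp=vjp)


def pow_const(a: Tensor, c: float) -> Tensor:
    def vjp(g):
        return (mul(g, mul(Tensor(np.float64(c)), pow_const(a, c - 1.0))),)

    return Tensor(a.data ** c, _parents=(a,), _vjp=vjp)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        ga = matmul(g, swapaxes(b, -1, -2))
        gb = matmul(swapaxes(a, -1, -2), g)
        return _sum_to(ga, a.shape), _sum_to(gb, b.shape)

    return Tensor(a.data @ b.data, _parents=(a, b), _vjp=vjp)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return Tensor(a.data.reshape(shape), _parents=(a,), _vjp=vjp)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def vjp(g):
        return (swapaxes(g, ax1, ax2),)

    return Tensor(np.swapaxes(a.data, ax1, ax2), _parents=(a,), _vjp=vjp)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g):
        kd_shape = tuple(
            1 if i in axes else s for i, s in enumerate(in_shape)
        )
        return (broadcast_to(reshape(g, kd_shape), in_shape),)

    return Tensor(
        a.data.sum(axis=axes, keepdims=keepdims), _parents=(a,), _vjp=vjp
    )


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.float64(1.0 / n)))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    old = a.shape

    def vjp(g):
        return (_sum_to(g, old),)

    return Tensor(np.broadcast_to(a.data, shape), _parents=(a,), _vjp=vjp)


def texp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = Tensor(out_data, _parents=(a,), _vjp=None)

    def vjp(g):
        return (mul(g, out),)

    out._vjp = vjp
    return out


def tlog(a: Tensor) -> Tensor:
    def vjp(g):
        return (mul(g, pow_const(a, -1.0)),)

    return Tensor(np.log(a.data), _parents=(a,), _vjp=vjp)


def tsqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), _parents=(a,), _vjp=None)

    def vjp(g):
        return (mul(g, mul(Tensor(np.float64(0.5)), pow_const(a, -0.5))),)

    out._vjp = vjp
    return out


def tabs(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def vjp(g):
        return (mul(g, Tensor(sign)),)

    return Tensor(np.abs(a.data), _parents=(a,), _vjp=vjp)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    out = Tensor(out_data, _parents=(a,), _vjp=None)

    def vjp(g):
        return (mul(g, add(Tensor(np.float64(1.0)), neg(mul(out, out)))),)

    out._vjp = vjp
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    # derivative is piecewise constant; treated as constant w.r.t. the input,
    # which is exact almost everywhere
    mask = np.where(a.data > 0, 1.0, slope)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return Tensor(np.where(a.data > 0, a.data, slope * a.data), _parents=(a,), _vjp=vjp)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    axis = axis % a.ndim
    sl = tuple(
        slice(start, start + length) if i == axis else slice(None)
        for i in range(a.ndim)
    )
    before, after = start, a.shape[axis] - start - length

    def vjp(g):
        return (pad_axis(g, axis, before, after),)

    return Tensor(a.data[sl], _parents=(a,), _vjp=vjp)


def pad_axis(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    axis = axis % a.ndim
    width = [(0, 0)] * a.ndim
    width[axis] = (before, after)
    length = a.shape[axis]

    def vjp(g):
        return (narrow(g, axis, before, length),)

    return Tensor(np.pad(a.data, width), _parents=(a,), _vjp=vjp)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes[:-1])

    def vjp(g):
        return tuple(
            narrow(g, axis, int(off), int(sz)) for off, sz in zip(offsets, sizes)
        )

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes by ``pad`` on every side."""
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]

    def vjp(g):
        return (crop2d(g, pad),)

    return Tensor(np.pad(a.data, width), _parents=(a,), _vjp=vjp)


def crop2d(a: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return a
    sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

    def vjp(g):
        return (pad2d(g, pad),)

    return Tensor(a.data[sl], _parents=(a,), _vjp=vjp)


def _unfold_np(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


def _fold_np(cols: np.ndarray, x_shape: tuple, k: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                cols[:, :, i, j]
            )
    return out


def unfold(a: Tensor, k: int, stride: int) -> Tensor:
    """im2col: (N, C, H, W) -> (N, C*k*k, L) column matrix."""
    x_shape = a.shape

    def vjp(g):
        return (fold(g, x_shape, k, stride),)

    return Tensor(_unfold_np(a.data, k, stride), _parents=(a,), _vjp=vjp)


def fold(a: Tensor, x_shape: tuple, k: int, stride: int) -> Tensor:
    """col2im scatter-add; the exact adjoint of :func:`unfold`."""

    def vjp(g):
        return (unfold(g, k, stride),)

    return Tensor(_fold_np(a.data, x_shape, k, stride), _parents=(a,), _vjp=vjp)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = a.data.max(axis=axis, keepdims=True)  # constant shift, exact
    e = texp(add(a, Tensor(-shift)))
    return mul(e, pow_const(tsum(e, axis=axis, keepdims=True), -1.0))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _topo(out: Tensor):
    order, seen, stack = [], set(), [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output: Tensor | None = None):
    """Cotangents of ``output`` w.r.t. each tensor in ``inputs``.

    The returned tensors are themselves graph nodes, so differentiating
    through them yields higher-order derivatives.
    """
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    cot: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(_topo(output)):
        g = cot.pop(id(node), None)
        if g is None or node._vjp is None:
            if g is not None:
                cot[id(node)] = g  # leaf: keep for lookup below
            continue
        keep = any(node is t for t in inputs)
        if keep:
            cot[id(node)] = g
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            prev = cot.get(id(p))
            cot[id(p)] = pg if prev is None else add(prev, pg)
    return [
        cot.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs
    ]
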