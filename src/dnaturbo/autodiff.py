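"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the codec's networks need are implemented: elementwise
arithmetic, matmul, 1-D same-padding convolution, reductions, indexing /
permutation, the usual activations, and the two estimator tricks the codec
depends on (straight-through binarization and a value-exact surrogate
gradient hook).  float32 throughout.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = _as_array(grad)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, pgrad in t._backward(t.grad):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(DTYPE, copy=True)
                else:
                    parent.grad = parent.grad + pgrad

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# -- primitives -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)),
                (b, _unbroadcast(g, b.data.shape)))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        return ((a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)))

    return _node(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1.0)),)

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return ((a, _unbroadcast(ga, a.data.shape)),
                (b, _unbroadcast(gb, b.data.shape)))

    return _node(out_data, (a, b), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: ((a, g * mask),))


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _wrap(a)
    neg = a.data < 0
    out_data = np.where(neg, alpha * (np.exp(np.minimum(a.data, 0)) - 1), a.data)

    def backward(g):
        return ((a, g * np.where(neg, out_data + alpha, 1.0)),)

    return _node(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)
    return _node(out_data, (a,), lambda g: ((a, g * (1 - out_data ** 2)),))


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out_data, (a,),
                 lambda g: ((a, g * out_data * (1 - out_data)),))


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)
    return _node(out_data, (a,), lambda g: ((a, g * out_data),))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape)),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(gg, a.data.shape)),)

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        count = a.data.size
    else:
        count = a.data.shape[axis]
    return mul(tsum(a, axis, keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape
    return _node(a.data.reshape(shape), (a,),
                 lambda g: ((a, g.reshape(old)),))


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)
    return _node(a.data.transpose(axes), (a,),
                 lambda g: ((a, g.transpose(inv)),))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _node(out_data, tuple(tensors), backward)


def take(a, indices: np.ndarray, axis: int = -1) -> Tensor:
    """Gather along ``axis`` — used for interleaver permutations."""
    a = _wrap(a)
    indices = np.asarray(indices, dtype=np.int64)
    out_data = np.take(a.data, indices, axis=axis)

    def backward(g):
        grad = np.zeros_like(a.data)
        # scatter-add back; for a permutation this is a plain scatter
        np.add.at(np.moveaxis(grad, axis, 0), indices, np.moveaxis(g, axis, 0))
        return ((a, grad),)

    return _node(out_data, (a,), backward)


def conv1d(x, w, b=None) -> Tensor:
    """Same-padding 1-D convolution.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K) with odd K; ``b``: (C_out,).
    """
    x, w = _wrap(x), _wrap(w)
    B, C, L = x.data.shape
    O, C2, K = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    P = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (P, P)))
    cols = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    )  # B,C,L,K
    # (B,C,L,K) x (O,C,K) over (C,K) -> (B,L,O)
    out_blo = np.tensordot(cols, w.data, axes=([1, 3], [1, 2]))
    out_data = np.ascontiguousarray(out_blo.transpose(0, 2, 1))
    if b is not None:
        out_data += b.data[None, :, None]

    def backward(g):
        gw = np.tensordot(g, cols, axes=([0, 2], [0, 2]))  # (O,C,K)
        gcols = np.tensordot(g, w.data, axes=([1], [0]))  # (B,L,C,K)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + L] += gcols[:, :, :, k].transpose(0, 2, 1)
        gx = gxp[:, :, P:P + L] if P else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((a, out_data * (g - dot)),)

    return _node(out_data, (a,), backward)


def binarize_ste(a, bipolar: bool = True) -> Tensor:
    """Sign-threshold at 0 forward; identity gradient backward."""
    a = _wrap(a)
    hard = (a.data >= 0).astype(DTYPE)
    out_data = 2.0 * hard - 1.0 if bipolar else hard
    return _node(out_data, (a,), lambda g: ((a, g),))


def surrogate_value(exact: float, surrogate: Tensor) -> Tensor:
    """A node whose value is ``exact`` but whose gradient is the surrogate's.

    Implements the value-correction trick ``exact + (s - stop_grad(s))`` used
    to attach a differentiable surrogate to a non-differentiable score.
    """
    surrogate = _wrap(surrogate)
    out_data = np.full_like(surrogate.data, exact)
    return _node(out_data, (surrogate,), lambda g: ((surrogate, g),))


def passthrough(a, forward_fn) -> Tensor:
    """Apply an arbitrary (non-differentiable) map forward; identity backward.

    ``forward_fn(np.ndarray) -> np.ndarray`` must preserve the array shape.
    Used to pass encoder activations through the simulated DNA channel while
    keeping a straight-through gradient path for encoder training.
    """
    a = _wrap(a)
    out_data = _as_array(forward_fn(a.data))
    if out_data.shape != a.data.shape:
        raise ValueError("passthrough forward must preserve shape")
    return _node(out_data, (a,), lambda g: ((a, g),))


def stop_gradient(a, forward_fn=None) -> Tensor:
    data = a.data if isinstance(a, Tensor) else _as_array(a)
    if forward_fn is not None:
        data = _as_array(forward_fn(data))
    return Tensor(data)


def smooth_l1(pred, target, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber-style) loss.

    Elementwise ``0.5*d^2/beta`` for ``|d| < beta`` else ``|d| - 0.5*beta``,
    averaged over all elements.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    pred = _wrap(pred)
    tgt = target.data if isinstance(target, Tensor) else _as_array(target)
    if pred.data.shape != tgt.shape:
        raise ValueError(
            f"shape mismatch: {pred.data.shape} vs {tgt.shape}"
        )
    d = pred.data - tgt
    absd = np.abs(d)
    quad = absd < beta
    elems = np.where(quad, 0.5 * d * d / beta, absd - 0.5 * beta)
    n = d.size
    out_data = np.array(elems.mean(), dtype=DTYPE)

    def backward(g):
        gd = np.where(quad, d / beta, np.sign(d)) / n
        return ((pred, g * gd),)

    return _node(out_data, (pred,), backward)
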