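"""Minimal tape-based reverse-mode autodiff over numpy arrays.

Supports exactly the operations the package's small networks need:
elementwise arithmetic, matmul, reductions, gather/segment-sum (for
per-node attention softmax on graphs), and 3D convolution / pooling /
nearest-neighbour upsampling primitives (for the CAM classifier and the
encoder-decoder segmenter).  Gradients flow only through ``Tensor``
nodes created with ``requires_grad=True`` or derived from them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            if a.ndim == 1:  # (k,) @ (k,n)
                return (g @ b.T, np.outer(a, g))
            if b.ndim == 1:  # (m,k) @ (k,)
                return (np.outer(g, b), a.T @ g)
            return (g @ b.T, a.T @ g)

        return Tensor._make(a @ b, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, e)

        def backward(g):
            return (g * np.where(pos, 1.0, e + alpha),)

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * s,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- shape / reduction ----------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.full(self.data.shape, g, dtype=np.float64),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.data.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            if t._backward is not None:   # leaves keep accumulating across calls
                t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


# -- free functions ------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, backward)


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Rows of `t` selected by integer `index` (along axis 0)."""
    index = np.asarray(index)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, index, g)
        return (out,)

    return Tensor._make(t.data[index], (t,), backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `t` into `n_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids)
    shape = (n_segments,) + t.data.shape[1:]
    data = np.zeros(shape, dtype=np.float64)
    np.add.at(data, segment_ids, t.data)

    def backward(g):
        return (g[segment_ids],)

    return Tensor._make(data, (t,), backward)
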