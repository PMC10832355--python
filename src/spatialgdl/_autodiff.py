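"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph deep-learning modules need:
dense/sparse matrix products, elementwise nonlinearities, reductions, row
gather/scatter and segment softmax for attention. Gradients flow through a
dynamically built tape; ``Tensor.backward()`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ arithmetic

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    # ------------------------------------------------------------------ nonlinearities

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: (np.where(mask, g, slope * g),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -500, 500))
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def softplus(self):
        # numerically stable log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        x = self.data
        val = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: (g * s,)
        return out

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: (2.0 * g * self.data,)
        return out

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    # ------------------------------------------------------------------ reductions / shape

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), parents=(self,))
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            ge = np.expand_dims(g, axis)
            return (np.broadcast_to(ge, self.data.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def gather_rows(self, idx: np.ndarray):
        """Select rows by integer index; backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))
        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return (acc,)
        out._backward = backward
        return out

    # ------------------------------------------------------------------ engine

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def spmm(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (tensor) product."""
    a = sp.csr_matrix(a)
    out = Tensor(a @ x.data, parents=(x,))
    at = a.T.tocsr()
    out._backward = lambda g: (at @ g,)
    return out


def segment_sum(values: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `values` into `n_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    shape = (n_segments,) + values.data.shape[1:]
    acc = np.zeros(shape)
    np.add.at(acc, segment_ids, values.data)
    out = Tensor(acc, parents=(values,))
    out._backward = lambda g: (g[segment_ids],)
    return out


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of per-edge scores within each destination-node segment.

    Stabilized by subtracting the per-segment max (a constant w.r.t. the
    gradient path, so it is applied to the raw data only).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    seg_max = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    shifted = scores - Tensor(seg_max[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, n_segments)
    return e * _reciprocal(denom.gather_rows(segment_ids))


def _reciprocal(t: Tensor) -> Tensor:
    out = Tensor(1.0 / t.data, parents=(t,))
    out._backward = lambda g: (-g / (t.data ** 2),)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
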