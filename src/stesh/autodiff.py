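"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is a full-graph multi-view GCN trained end-to-end;
the operation set here (broadcasted arithmetic, dense and sparse matrix
products, ReLU/tanh/sigmoid/softplus, log-gamma, reductions) is exactly what
the encoder, attention fusion, negative-binomial decoder and loss terms need.
Gradients are accumulated by topological-order backpropagation; correctness
is established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sparse
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "as_tensor", "spmm", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    # make `ndarray <op> Tensor` dispatch to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._grad_fns: tuple = ()

    # ---- graph plumbing -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, grad_fns) -> "Tensor":
        keep = [(p, g) for p, g in zip(parents, grad_fns) if p.requires_grad]
        out = cls(data, requires_grad=bool(keep))
        if keep:
            out._parents = tuple(p for p, _ in keep)
            out._grad_fns = tuple(g for _, g in keep)
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, gf in zip(node._parents, node._grad_fns):
                pg = gf(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                elif p._parents:
                    grads[id(p)] = pg
                else:
                    p.grad = pg if p.grad is None else p.grad + pg

    # ---- basic properties ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return Tensor._from_op(self.data.T, (self,), (lambda g: g.T,))

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor._from_op(
            self.data + o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(g, o.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor._from_op(
            self.data * o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g * o.data, self.data.shape),
                lambda g: _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor._from_op(
            self.data / o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g / o.data, self.data.shape),
                lambda g: _unbroadcast(-g * self.data / o.data**2, o.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor._from_op(
            self.data**p, (self,), (lambda g: g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other):
        o = as_tensor(other)
        return Tensor._from_op(
            self.data @ o.data,
            (self, o),
            (lambda g: g @ o.data.T, lambda g: self.data.T @ g),
        )

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ---- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), (lambda g: g * mask,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._from_op(t, (self,), (lambda g: g * (1.0 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._from_op(e, (self,), (lambda g: g * e,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), (lambda g: g / self.data,))

    def sqrt(self):
        s = np.sqrt(self.data)
        return Tensor._from_op(s, (self,), (lambda g: g * 0.5 / s,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(s, (self,), (lambda g: g * s * (1.0 - s),))

    def softplus(self):
        # log(1 + e^x), computed stably; derivative is sigmoid(x)
        x = self.data
        e = np.exp(-np.abs(x))  # shared between value and derivative
        out = np.maximum(x, 0) + np.log1p(e)
        sig = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._from_op(out, (self,), (lambda g: g * sig,))

    def gammaln(self):
        return Tensor._from_op(
            _gammaln(self.data), (self,), (lambda g: g * _digamma(self.data),)
        )

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._from_op(
            np.clip(self.data, lo, hi), (self,), (lambda g: g * mask,)
        )

    def take_pairs(self, rows, cols):
        """Gather entries at (rows[i], cols[i]); scatter-adds on backward."""

        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, (rows, cols), g)
            return out

        return Tensor._from_op(self.data[rows, cols], (self,), (grad_fn,))

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor._from_op(out, (self,), (grad_fn,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a_sparse, x: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product (adjacency propagation)."""
    if not sparse.issparse(a_sparse):
        raise TypeError("spmm expects a scipy.sparse matrix on the left")
    at = a_sparse.T.tocsr()
    return Tensor._from_op(a_sparse @ x.data, (x,), (lambda g: at @ g,))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class Adam:
    """Adam optimizer with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
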