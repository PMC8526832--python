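"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains a transformer encoder jointly with variational Gaussian
process heads, which needs gradients through dense linear algebra (including
Cholesky factorizations and triangular solves) as well as the usual neural
network primitives.  This module provides exactly that: a small, vectorized
tape-based autodiff engine.  Every operation stores a backward closure; calling
:meth:`Tensor.backward` accumulates gradients in topological order.

Only the operations the package actually uses are implemented.  Gradient
correctness is enforced by finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.linalg as sla
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "stack",
    "matmul",
    "cholesky",
    "tri_solve",
    "take_rows",
    "where_const",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        """Accumulate a gradient that may alias another buffer (copies once)."""
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a freshly allocated gradient (takes ownership)."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    ga = _unbroadcast(g, a.shape)
                    a._accumulate(ga) if ga is g else a._accumulate_owned(ga)
                if b.requires_grad or b._parents:
                    gb = _unbroadcast(g, b.shape)
                    b._accumulate(gb) if gb is g else b._accumulate_owned(gb)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate_owned(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate_owned(_unbroadcast(g * b.data, a.shape))
                if b.requires_grad or b._parents:
                    b._accumulate_owned(_unbroadcast(g * a.data, b.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate_owned(_unbroadcast(g / b.data, a.shape))
                if b.requires_grad or b._parents:
                    b._accumulate_owned(_unbroadcast(-g * a.data / b.data**2, b.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))
        if out._parents:
            out._backward = lambda g, a=self, p=exponent: a._accumulate_owned(
                g * p * a.data ** (p - 1)
            )
        return out

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out._parents:
            def bwd(g, a=self, i=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, i, g)
                a._accumulate_owned(full)
            out._backward = bwd
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate_owned(g * v)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate_owned(g / a.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = _node(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate_owned(g / (2.0 * v))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _node(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate_owned(g * (1.0 - v**2))
        return out

    def sigmoid(self):
        val = _sigmoid(self.data)
        out = _node(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate_owned(g * v * (1.0 - v))
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = _node(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate_owned(g * _sigmoid(a.data))
        return out

    def erf(self):
        out = _node(_erf(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate_owned(
                g * 2.0 / np.sqrt(np.pi) * np.exp(-a.data**2)
            )
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient is zero where clipped."""
        mask = self.data > lo
        out = _node(np.where(mask, self.data, lo), (self,))
        if out._parents:
            out._backward = lambda g, a=self, m=mask: a._accumulate_owned(g * m)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bwd(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accumulate_owned(np.broadcast_to(g, a.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(g.reshape(a.shape))
        return out

    def swapaxes(self, a1: int, a2: int):
        out = _node(self.data.swapaxes(a1, a2), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(g.swapaxes(a2, a1))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (fast inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data @ b.data, (a, b))
    if out._parents:
        def bwd(g, a=a, b=b):
            if a.requires_grad or a._parents:
                ga = g @ b.data.swapaxes(-1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
                a._accumulate_owned(_unbroadcast(ga, a.shape))
            if b.requires_grad or b._parents:
                if a.data.ndim > 1:
                    gb = a.data.swapaxes(-1, -2) @ g
                else:
                    gb = np.outer(a.data, g)
                b._accumulate_owned(_unbroadcast(gb, b.shape))
        out._backward = bwd
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(g, sp, axis=ax)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)
        out._backward = bwd
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        def bwd(g, ts=tensors, ax=axis):
            for i, t in enumerate(ts):
                if t.requires_grad or t._parents:
                    t._accumulate(np.take(g, i, axis=ax))
        out._backward = bwd
    return out


def take_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of a 2-D table by an integer index array (embedding lookup)."""
    index = np.asarray(index)
    out = _node(table.data[index], (table,))
    if out._parents:
        def bwd(g, t=table, idx=index):
            full = np.zeros_like(t.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, t.data.shape[1]))
            t._accumulate_owned(full)
        out._backward = bwd
    return out


def where_const(cond: np.ndarray, a: Tensor, fill: float) -> Tensor:
    """a where cond else fill (fill is a constant; used for attention masking)."""
    cond = np.asarray(cond, dtype=bool)
    out = _node(np.where(cond, a.data, fill), (a,))
    if out._parents:
        out._backward = lambda g, t=a, c=cond: t._accumulate_owned(
            _unbroadcast(g * c, t.shape)
        )
    return out


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis, with fused backward."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    ex = np.exp(shifted)
    y = ex / ex.sum(axis=-1, keepdims=True)
    out = _node(y, (x,))
    if out._parents:
        def bwd(g, t=x, yv=y):
            inner = (g * yv).sum(axis=-1, keepdims=True)
            t._accumulate_owned((g - inner) * yv)
        out._backward = bwd
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error GELU with fused backward."""
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    cdf = 0.5 * (1.0 + _erf(x.data * inv_sqrt2))
    out = _node(x.data * cdf, (x,))
    if out._parents:
        def bwd(g, t=x, c=cdf):
            pdf = np.exp(-0.5 * t.data**2) / np.sqrt(2.0 * np.pi)
            t._accumulate_owned(g * (c + t.data * pdf))
        out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Last-axis layer normalization with fused backward."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_sd
    out = _node(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out._parents:
        def bwd(g, t=x, gm=gamma, bt=beta, xh=xhat, isd=inv_sd):
            if gm.requires_grad or gm._parents:
                gm._accumulate_owned(
                    _unbroadcast(g * xh, gm.shape)
                )
            if bt.requires_grad or bt._parents:
                bt._accumulate_owned(_unbroadcast(g, bt.shape))
            if t.requires_grad or t._parents:
                gx = g * gm.data
                m1 = gx.mean(axis=-1, keepdims=True)
                m2 = (gx * xh).mean(axis=-1, keepdims=True)
                t._accumulate_owned((gx - m1 - xh * m2) * isd)
        out._backward = bwd
    return out


def _phi(x: np.ndarray) -> np.ndarray:
    """Lower triangle with halved diagonal (Cholesky reverse-mode helper)."""
    out = np.tril(x)
    out[np.diag_indices_from(out)] *= 0.5
    return out


def cholesky(a: Tensor, jitter: float = 0.0) -> Tensor:
    """Lower Cholesky factor of a symmetric PSD matrix, with reverse mode.

    Raises ``np.linalg.LinAlgError`` (suggesting jitter) if the factorization
    fails even after adding `jitter` to the diagonal.
    """
    mat = a.data
    if jitter:
        mat = mat + jitter * np.eye(mat.shape[-1])
    try:
        chol_val = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "Cholesky factorization failed; matrix may need jitter on the diagonal"
        ) from exc
    out = _node(chol_val, (a,))
    if out._parents:
        def bwd(g, t=a, L=chol_val):
            p = _phi(L.T @ g)
            z = sla.solve_triangular(L, p, lower=True, trans="T")
            abar = sla.solve_triangular(L, z.T, lower=True, trans="T").T
            t._accumulate(0.5 * (abar + abar.T))
        out._backward = bwd
    return out


def tri_solve(chol_l: Tensor, rhs: Tensor) -> Tensor:
    """Solve L Y = B with L lower-triangular; differentiable in both arguments."""
    y_val = sla.solve_triangular(chol_l.data, rhs.data, lower=True)
    out = _node(y_val, (chol_l, rhs))
    if out._parents:
        def bwd(g, lt=chol_l, bt=rhs, y=y_val):
            gb = sla.solve_triangular(lt.data, g, lower=True, trans="T")
            if bt.requires_grad or bt._parents:
                bt._accumulate(gb)
            if lt.requires_grad or lt._parents:
                lt._accumulate(-np.tril(gb @ y.T))
        out._backward = bwd
    return out


class Adam:
    """Adam optimizer with decoupled weight decay applied to selected parameters."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 3e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_params: Sequence[Parameter] | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        decay_ids = {id(p) for p in (decay_params if decay_params is not None else self.params)}
        self._decay = [id(p) in decay_ids for p in self.params]
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g**2
            mhat = self._m[i] / (1 - self.b1**self._t)
            vhat = self._v[i] / (1 - self.b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decay[i]:
                # decoupled decay: applied to the weights directly, never fed
                # through the adaptive normalizer (which would let the decay
                # direction crush parameters with small data gradients)
                p.data -= self.lr * self.weight_decay * p.data
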