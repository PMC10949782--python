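"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free, recursion-free autograd: each :class:`Tensor` records its parents
and a closure that accumulates gradients into them.  Supports exactly the
operations the bundled models need (dense/sparse matmul, broadcasting
arithmetic, the usual nonlinearities, ``gammaln`` for count likelihoods) and an
Adam optimizer.  Everything is float64 and CPU-only, which keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln as _gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal -------------------------------------------------
    def backward(self):
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _const(-1.0)))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _const(x) -> Tensor:
    return Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.value.shape)
    t.grad = g if t.grad is None else t.grad + g


# -- primitive ops -------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, parents=(a, b))
    if out.requires_grad:
        out._backward = lambda g: (_accum(a, g), _accum(b, g))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, parents=(a, b))
    if out.requires_grad:
        out._backward = lambda g: (_accum(a, g * b.value), _accum(b, g * a.value))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, parents=(a, b))
    if out.requires_grad:
        out._backward = lambda g: (_accum(a, g @ b.value.T), _accum(b, a.value.T @ g))
    return out


def spmm(A, x: Tensor) -> Tensor:
    """Constant sparse matrix times differentiable dense matrix."""
    A = sp.csr_matrix(A)
    out = Tensor(A @ x.value, parents=(x,))
    if out.requires_grad:
        AT = A.T.tocsr()
        out._backward = lambda g: _accum(x, AT @ g)
    return out


def power(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.value ** p, parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: _accum(a, g * p * a.value ** (p - 1))
    return out


def exp(a: Tensor) -> Tensor:
    v = np.exp(np.clip(a.value, -700, 700))
    out = Tensor(v, parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: _accum(a, g * v)
    return out


def log(a: Tensor, eps: float = 0.0) -> Tensor:
    out = Tensor(np.log(a.value + eps), parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: _accum(a, g / (a.value + eps))
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.value, 0.0), parents=(a,))
    if out.requires_grad:
        mask = (a.value > 0).astype(np.float64)
        out._backward = lambda g: _accum(a, g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    v = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500, 500)))
    out = Tensor(v, parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: _accum(a, g * v * (1 - v))
    return out


def softplus(a: Tensor) -> Tensor:
    x = a.value
    v = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))
    out = Tensor(v, parents=(a,))
    if out.requires_grad:
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        out._backward = lambda g: _accum(a, g * s)
    return out


def gammaln(a: Tensor) -> Tensor:
    out = Tensor(_gammaln(a.value), parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: _accum(a, g * digamma(a.value))
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), parents=(a,))
    if out.requires_grad:
        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(a, np.broadcast_to(gg, a.value.shape).copy())
        out._backward = bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), _const(1.0 / n))


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = Tensor(a.value[idx], parents=(a,))
    if out.requires_grad:
        def bw(g):
            acc = np.zeros_like(a.value)
            np.add.at(acc, idx, g)
            _accum(a, acc)
        out._backward = bw
    return out


def log_softmax(a: Tensor) -> Tensor:
    """Row-wise log-softmax, numerically stabilized by the row max (treated as constant)."""
    m = a.value.max(axis=1, keepdims=True)
    shifted = add(a, _const(-m))
    lse = log(tsum(exp(shifted), axis=1, keepdims=True))
    return add(shifted, mul(lse, _const(-1.0)))


# -- parameters and optimization ----------------------------------------

def param(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return param(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class Adam:
    """Plain Adam (no weight decay); float64 state for reproducibility."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

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
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
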