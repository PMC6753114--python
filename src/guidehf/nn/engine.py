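"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the recurrent and convolutional regressors:
tensors carry a value, an optional gradient, and a closure that routes the
upstream gradient to their parents. Gradients are accumulated by a reverse
topological sweep from the loss. Every op is gradient-checked numerically in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "param", "const"]


class Tensor:
    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], Iterable[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return add(self, mulc(_wrap(other), -1.0))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    # -- backward sweep ---------------------------------------------------
    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() expects a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad += g


def param(value: np.ndarray) -> Tensor:
    return Tensor(np.asarray(value, dtype=float), requires_grad=True)


def const(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=float))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else const(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# -- primitive ops --------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value * b.value

    def backward(g):
        return _unbroadcast(g * b.value, a.shape), _unbroadcast(g * a.value, b.shape)

    return Tensor(out, (a, b), backward)


def mulc(a: Tensor, c: float) -> Tensor:
    return Tensor(a.value * c, (a,), lambda g: (g * c,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value @ b.value

    def backward(g):
        return g @ b.value.T, a.value.T @ g

    return Tensor(out, (a, b), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.value))
    return Tensor(s, (a,), lambda g: (g * s * (1.0 - s),))


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.value)
    return Tensor(t, (a,), lambda g: (g * (1.0 - t * t),))


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0

    def backward(g):
        return (g * mask,)

    return Tensor(a.value * mask, (a,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.shape
    return Tensor(a.value.reshape(shape), (a,), lambda g: (g.reshape(orig),))


def mean(a: Tensor) -> Tensor:
    n = a.value.size

    def backward(g):
        return (np.full_like(a.value, float(g) / n),)

    return Tensor(np.asarray(a.value.mean()), (a,), backward)


def square(a: Tensor) -> Tensor:
    return Tensor(a.value**2, (a,), lambda g: (2.0 * g * a.value,))


def dropout(a: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return a
    keep = (rng.random(a.shape) >= rate) / (1.0 - rate)

    def backward(g):
        return (g * keep,)

    return Tensor(a.value * keep, (a,), backward)


def conv1d(x: Tensor, w: Tensor) -> Tensor:
    """Valid 1-D convolution. x: (B, L, C); w: (K, C, F) -> (B, L-K+1, F)."""
    B, L, C = x.shape
    K, _, F = w.shape
    Lout = L - K + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.value, K, axis=1)
    # windows: (B, Lout, C, K) -> contract over (C, K)
    out = np.einsum("blck,kcf->blf", windows, w.value)

    def backward(g):
        gw = np.einsum("blck,blf->kcf", windows, g)
        gx = np.zeros_like(x.value)
        for k in range(K):
            gx[:, k : k + Lout, :] += g @ w.value[k].T
        return gx, gw

    return Tensor(out, (x, w), backward)
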