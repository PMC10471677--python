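"""Minimal vectorized reverse-mode automatic differentiation.

The package trains a small full-batch graph model, so the engine only
implements the handful of dense operations that model needs: matrix
multiplication, broadcast add/multiply, ReLU/tanh/sigmoid, softmax,
clamped log, row gather/concat, reductions, dropout-by-mask and the
gradient-reversal layer (identity forward, gradient scaled by -lambda
backward). Gradients are accumulated by a topological sweep over the
recorded tape, and an Adam optimizer updates parameters in place.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "softmax",
    "log",
    "concat_rows",
    "take_rows",
    "mean",
    "total",
    "gradient_reversal",
    "dropout_mask",
    "glorot_uniform",
    "Adam",
]

_LOG_EPS = 1e-12


class Tensor:
    """Array node on the autodiff tape.

    ``data`` is a float64 ndarray; ``grad`` is filled by :meth:`backward`
    for nodes with ``requires_grad``. Operations build the tape eagerly.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic arithmetic -------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    def __neg__(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            _accum(self, -g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- backward sweep ---------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep-ish
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(a.data @ b.data, parents=(a, b), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * (1.0 - out * out))

    return Tensor(out, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        dot = (g * out).sum(axis=axis, keepdims=True)
        _accum(x, out * (g - dot))

    return Tensor(out, parents=(x,), backward=bwd)


def log(x: Tensor, eps: float = _LOG_EPS) -> Tensor:
    """Natural log with the argument clamped below at ``eps``."""
    clipped = np.maximum(x.data, eps)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g / clipped)

    return Tensor(np.log(clipped), parents=(x,), backward=bwd)


def concat_rows(parts: Sequence[Tensor]) -> Tensor:
    sizes = [p.data.shape[0] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            _accum(p, g[lo:hi])

    return Tensor(np.concatenate([p.data for p in parts], axis=0),
                  parents=tuple(parts), backward=bwd)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            _accum(x, acc)

    return Tensor(x.data[idx], parents=(x,), backward=bwd)


def gather_cols(x: Tensor, cols: np.ndarray) -> Tensor:
    """Pick one column per row: out[i] = x[i, cols[i]]."""
    cols = np.asarray(cols, dtype=np.intp)
    rows = np.arange(x.data.shape[0])

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[rows, cols] = g
            _accum(x, acc)

    return Tensor(x.data[rows, cols], parents=(x,), backward=bwd)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g: np.ndarray) -> None:
        _accum(x, np.full_like(x.data, float(g) / n))

    return Tensor(x.data.mean(), parents=(x,), backward=bwd)


def total(x: Tensor) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        _accum(x, np.full_like(x.data, float(g)))

    return Tensor(x.data.sum(), parents=(x,), backward=bwd)


def gradient_reversal(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; backward multiplies the gradient by -lam."""

    def bwd(g: np.ndarray) -> None:
        _accum(x, -lam * g)

    return Tensor(x.data.copy(), parents=(x,), backward=bwd)


def dropout_mask(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero entries with prob ``p``, rescale survivors."""
    if p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * constant(keep)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam with the usual bias-corrected first/second moment estimates."""

    def __init__(self, params: Iterable[Tensor], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
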