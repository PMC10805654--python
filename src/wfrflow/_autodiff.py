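"""Minimal reverse-mode automatic differentiation over numpy arrays.

The loss of the dynamic unbalanced optimal-transport problem is a scalar
function of the parameters of two small multilayer perceptrons, reached
through a Runge-Kutta discretization of the characteristic ODEs.  The op set
below is exactly what that computation needs (affine maps, tanh, batched
matrix products for input-Jacobians, log-sum-exp for Gaussian-mixture log
densities, and elementwise arithmetic with broadcasting); it is deliberately
not a general tensor library.

Gradients are accumulated by a single reverse topological sweep
(:meth:`Tensor.backward`).  Correctness is pinned down by finite-difference
tests in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "affine",
    "tanh",
    "exp",
    "square",
    "mat_bmm",
    "bmm",
    "transpose2d",
    "slice_rows",
    "btrace",
    "concat_cols",
    "concat_rows",
    "slice_cols",
    "reshape",
    "reduce_sum",
    "reduce_mean",
    "logsumexp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, parents=(), vjp=None, requires_grad=False):
        if type(value) is not np.ndarray or value.dtype != np.float64:
            value = np.asarray(value, dtype=np.float64)
        self.value = value
        self.grad = None
        self._parents = parents
        self._vjp = vjp
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    # ------------------------------------------------------------- backward
    def backward(self, seed: np.ndarray | None = None) -> None:
        if seed is None:
            if self.value.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.value)
        # iterative topological sort
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._vjp(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy() if pgrad.base is not None else pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _wrap(other)
        out_val = self.value + other.value
        a_shape, b_shape = self.value.shape, other.value.shape
        return Tensor(
            out_val,
            parents=(self, other),
            vjp=lambda g: (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        a, b = self, other
        out_val = a.value * b.value
        return Tensor(
            out_val,
            parents=(a, b),
            vjp=lambda g: (
                _unbroadcast(g * b.value, a.value.shape),
                _unbroadcast(g * a.value, b.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; multiply by inverse")
        return self * (1.0 / float(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


# ------------------------------------------------------------------ op set
def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x @ W + b with x of shape (n, p), W (p, q), b (q,)."""
    out = x.value @ W.value + b.value

    def vjp(g):
        return (g @ W.value.T, x.value.T @ g, g.sum(axis=0))

    return Tensor(out, parents=(x, W, b), vjp=vjp)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.value)
    return Tensor(y, parents=(x,), vjp=lambda g: (g * (1.0 - y * y),))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.value)
    return Tensor(y, parents=(x,), vjp=lambda g: (g * y,))


def square(x: Tensor) -> Tensor:
    return Tensor(x.value * x.value, parents=(x,), vjp=lambda g: (2.0 * g * x.value,))


def mat_bmm(W: Tensor, T: Tensor) -> Tensor:
    """Left-multiply a batch of matrices by one matrix: (a,b) x (n,b,c) -> (n,a,c)."""
    out = np.matmul(W.value, T.value)

    def vjp(g):
        gW = np.matmul(g, T.value.transpose(0, 2, 1)).sum(axis=0)
        gT = np.matmul(W.value.T, g)
        return (gW, gT)

    return Tensor(out, parents=(W, T), vjp=vjp)


def bmm(A: Tensor, B: Tensor) -> Tensor:
    """Batched matmul (n,a,b) x (n,b,c) -> (n,a,c)."""
    out = np.matmul(A.value, B.value)

    def vjp(g):
        gA = np.matmul(g, B.value.transpose(0, 2, 1))
        gB = np.matmul(A.value.transpose(0, 2, 1), g)
        return (gA, gB)

    return Tensor(out, parents=(A, B), vjp=vjp)


def btrace(T: Tensor) -> Tensor:
    """Trace of each matrix in a (n, d, d) batch -> (n,)."""
    n, d, _ = T.value.shape
    out = np.trace(T.value, axis1=1, axis2=2)

    def vjp(g):
        gT = np.zeros_like(T.value)
        idx = np.arange(d)
        gT[:, idx, idx] = g[:, None]
        return (gT,)

    return Tensor(out, parents=(T,), vjp=vjp)


def concat_cols(parts: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis=1."""
    out = np.concatenate([p.value for p in parts], axis=1)
    widths = [p.value.shape[1] for p in parts]
    splits = np.cumsum(widths)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=1))

    return Tensor(out, parents=tuple(parts), vjp=vjp)


def concat_rows(parts: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis=0."""
    out = np.concatenate([p.value for p in parts], axis=0)
    heights = [p.value.shape[0] for p in parts]
    splits = np.cumsum(heights)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=0))

    return Tensor(out, parents=tuple(parts), vjp=vjp)


def slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    out = x.value[:, a:b]

    def vjp(g):
        gx = np.zeros_like(x.value)
        gx[:, a:b] = g
        return (gx,)

    return Tensor(out, parents=(x,), vjp=vjp)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.value.shape
    return Tensor(
        x.value.reshape(shape), parents=(x,), vjp=lambda g: (g.reshape(orig),)
    )


def transpose2d(x: Tensor) -> Tensor:
    return Tensor(x.value.T, parents=(x,), vjp=lambda g: (g.T,))


def slice_rows(x: Tensor, a: int, b: int) -> Tensor:
    out = x.value[a:b, :]

    def vjp(g):
        gx = np.zeros_like(x.value)
        gx[a:b, :] = g
        return (gx,)

    return Tensor(out, parents=(x,), vjp=vjp)


def reduce_sum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = x.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, x.value.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, x.value.shape).copy(),)

    return Tensor(out, parents=(x,), vjp=vjp)


def reduce_mean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = x.value.size
    else:
        n = x.value.shape[axis]
    return reduce_sum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def logsumexp(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-sum-exp along `axis` of a 2-D tensor."""
    m = x.value.max(axis=axis, keepdims=True)
    ex = np.exp(x.value - m)
    s = ex.sum(axis=axis)
    out = np.log(s) + m.squeeze(axis)

    def vjp(g):
        soft = ex / s[..., None] if axis == 1 else ex / s
        return (np.expand_dims(g, axis) * soft,)

    return Tensor(out, parents=(x,), vjp=vjp)
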