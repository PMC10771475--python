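"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Supports exactly the operations the message-passing score network needs:
dense affine maps, elementwise arithmetic with broadcasting, shifted
softplus, row gather/scatter (for graph message passing), concatenation and
reductions.  Gradients are accumulated by reverse topological traversal.

Correctness is established against central-difference oracles in the test
suite; the engine is deliberately eager and unoptimized — desk-scale graphs
(tens of atoms, hundreds of edges) are the intended regime.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "shifted_softplus", "concat", "gather_rows", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _make(value, parents, backward) -> "Tensor":
        out = Tensor(value, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of a scalar (or given seed) into the graph."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (7 layers x MLPs)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- operations -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g * other.value)
            other._accum(g * self.value)

        return Tensor._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g @ other.value.T)
            other._accum(self.value.T @ g)

        return Tensor._make(self.value @ other.value, (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)

    def square(self) -> "Tensor":
        return self * self

    def sum(self) -> "Tensor":
        def backward(g):
            self._accum(np.broadcast_to(g, self.value.shape))

        return Tensor._make(self.value.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        return self.sum() / self.value.size

    def reshape(self, *shape) -> "Tensor":
        old = self.value.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.value.reshape(*shape), (self,), backward)


def shifted_softplus(x: Tensor) -> Tensor:
    """ln(0.5 e^x + 0.5): the SchNet activation; ssp(0) = 0."""
    v = np.logaddexp(0.0, x.value) - np.log(2.0)

    def backward(g):
        x._accum(g * (1.0 / (1.0 + np.exp(-x.value))))

    return Tensor._make(v, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (gradient splits back)."""
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), backward
    )


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; the adjoint scatter-adds into the source."""
    index = np.asarray(index, dtype=np.int64)

    def backward(g):
        acc = np.zeros_like(x.value)
        np.add.at(acc, index, g)
        x._accum(acc)

    return Tensor._make(x.value[index], (x,), backward)


def segment_sum(x: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row bucket ids.

    The order-independent aggregation of messages onto nodes.
    """
    index = np.asarray(index, dtype=np.int64)
    out = np.zeros((n_segments,) + x.value.shape[1:])
    np.add.at(out, index, x.value)

    def backward(g):
        x._accum(g[index])

    return Tensor._make(out, (x,), backward)
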