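"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives needed by the model family in
this package are implemented (elementwise arithmetic, matmul with batch
dimensions, reductions, exp/log/tanh/sigmoid/relu, reshape/transpose/concat,
and a masked softmax).  All arithmetic is float64 so runs are deterministic
on a single thread and finite-difference gradient checks are tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev), _prev=prev)
        if out.requires_grad:
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from long LSTM rollouts recurse deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        prev = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, prev, backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        prev = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, prev, backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        prev = (self, other)
        denom = other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / denom, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / denom**2, other.shape))

        return self._make(self.data / denom, prev, backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        prev = (self, other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, prev, backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def masked_softmax(self, mask: np.ndarray, axis: int = -1) -> "Tensor":
        """Softmax along `axis` restricted to positions where `mask` is 1.

        Masked positions receive probability exactly 0 and propagate no
        gradient.  If every position along `axis` is masked the output row is
        all zeros (callers are expected to flag that case).
        """
        mask = np.asarray(mask, dtype=bool)
        neg = np.where(mask, self.data, -np.inf)
        m = np.max(neg, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)  # all-masked rows: avoid inf-inf
        e = np.where(mask, np.exp(self.data - m), 0.0)
        z = e.sum(axis=axis, keepdims=True)
        safe_z = np.where(z > 0, z, 1.0)
        out_data = e / safe_z

        def backward(g):
            # d softmax: s * (g - sum(g*s))
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _prev=tuple(tensors),
    )
    if out.requires_grad:
        out._backward = backward
    return out
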