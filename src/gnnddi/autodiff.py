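"""Minimal tape-based reverse-mode automatic differentiation on NumPy arrays.

The drug encoder and the pair classifier are small dense networks operating
on molecules with tens of atoms, so a compact tape (a ``Tensor`` wrapper
holding a value, a gradient buffer and a backward closure) is sufficient.
Only the operations those networks need are provided: broadcast-aware
add/mul, matmul, ReLU / LeakyReLU, exp, log, axis sums, concatenation, row
gathering and clipping.  Gradient correctness is enforced by central-finite-
difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "softmax_rows",
           "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape.

    Wraps a float64 ndarray.  Operations between tensors (or tensors and
    plain arrays/scalars) build the tape; :meth:`backward` walks it in
    reverse topological order and accumulates gradients into ``.grad`` of
    every tensor with ``requires_grad=True``.
    """

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

        return self._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g * b.value)
            if b.requires_grad:
                b._accumulate(g * a.value)

        return self._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g / b.value)
            if b.requires_grad:
                b._accumulate(-g * a.value / b.value**2)

        return self._make(self.value / other.value, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.value.T)
            if b.requires_grad:
                b._accumulate(a.value.T @ g)

        return self._make(self.value @ other.value, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.value > 0

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(self.value * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.value > 0
        factor = np.where(pos, 1.0, slope)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * factor)

        return self._make(self.value * factor, (self,), backward)

    def exp(self):
        out_val = np.exp(self.value)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * out_val)

        return self._make(out_val, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.value)

        return self._make(np.log(self.value), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        inside = (self.value > lo) & (self.value < hi)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * inside)

        return self._make(np.clip(self.value, lo, hi), (self,), backward)

    # -- reductions and reshaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.value.shape))

        return self._make(
            self.value.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(np.asarray(g).reshape(a.value.shape))

        return self._make(self.value.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(np.asarray(g).T)

        return self._make(self.value.T, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable ``requires_grad`` leaf."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; tapes can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors):
        g = np.asarray(g)
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(tensor: Tensor, indices) -> Tensor:
    """Select rows ``tensor[indices]`` (duplicates allowed; grads accumulate)."""
    indices = np.asarray(indices, dtype=np.intp)

    def backward(g, a=tensor):
        if a.requires_grad:
            buf = np.zeros_like(a.value)
            np.add.at(buf, indices, np.asarray(g))
            a._accumulate(buf)

    return tensor._make(tensor.value[indices], (tensor,), backward)


def segment_sum(values: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows (or scalars) of ``values`` into ``num_segments`` buckets.

    Segments with no members sum to zero.  Gradient scatters back by index.
    """
    values = Tensor._wrap(values)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_shape = (num_segments,) + values.value.shape[1:]
    out_val = np.zeros(out_shape)
    np.add.at(out_val, segment_ids, values.value)

    def backward(g, a=values):
        if a.requires_grad:
            a._accumulate(np.asarray(g)[segment_ids])

    return values._make(out_val, (values,), backward)


def softmax_rows(logits: Tensor) -> Tensor:
    """Row-wise softmax, stabilized by subtracting the detached row maximum."""
    shift = logits.value.max(axis=-1, keepdims=True)  # constant w.r.t. the tape
    e = (logits - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a fixed list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)
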