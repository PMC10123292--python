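"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the network needs: dense algebra
(matmul, broadcast add/mul/div), the nonlinearities (sigmoid, tanh,
ReLU/leaky-ReLU/ELU, exp, log), reductions, row gather, and segment
sum — the last two carry messages along graph edges and pool atoms
into molecules. Gradients are accumulated in float64; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "gather", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _acc(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._acc(g @ other.data.T)
            if other.requires_grad:
                other._acc(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._acc(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._acc(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, alpha)

        def backward(g):
            if self.requires_grad:
                self._acc(g * slope)

        return self._make(self.data * slope, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        ex = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, ex)

        def backward(g):
            if self.requires_grad:
                self._acc(g * np.where(pos, 1.0, ex + alpha))

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * e)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient flows only through unclipped entries."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._acc(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._acc(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- reductions -------------------------------------------------------------
    def sum(self, axis=None) -> "Tensor":
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._acc(np.full_like(self.data, 1.0) * g)
                else:
                    self._acc(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; callers skip this entirely in evaluation mode."""
        if p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def backward(g):
            if self.requires_grad:
                self._acc(g * keep)

        return self._make(self.data * keep, (self,), backward)

    # -- autograd driver ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A leaf tensor that the optimizer updates."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._acc(g[tuple(sl)])

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection t[idx]; scatter-adds the gradient back."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx])
    out.requires_grad = t.requires_grad
    if out.requires_grad:

        def backward(g):
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._acc(acc)

        out._parents = (t,)
        out._backward = backward
    return out


def segment_sum(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `t` into `n_segments` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    shape = (n_segments,) + t.data.shape[1:]
    data = np.zeros(shape)
    np.add.at(data, segments, t.data)
    out = Tensor(data)
    out.requires_grad = t.requires_grad
    if out.requires_grad:

        def backward(g):
            t._acc(g[segments])

        out._parents = (t,)
        out._backward = backward
    return out


def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax within each segment (per-row segment ids; rows are 1-D logits).

    Numerically stabilised by the per-segment max, which is treated as a
    constant (its subgradient contribution cancels in the softmax).
    """
    segments = np.asarray(segments, dtype=np.intp)
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, logits.data)
    shifted = logits + Tensor(-seg_max[segments])
    z = shifted.exp()
    denom = segment_sum(z, segments, n_segments)
    return z / gather(denom, segments)


class Adam:
    """Adam optimizer with optional gradient clipping by global norm."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
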