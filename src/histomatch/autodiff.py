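"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training stack in this package (tiny transformer encoders, cross-attention
matching, distillation and ranking losses) needs gradients for a few dozen
array primitives and nothing else, so the engine is deliberately small: a
:class:`Tensor` wraps an ``ndarray``, records its parents and a backward
closure, and :meth:`Tensor.backward` runs a topological sweep.  Broadcasting
follows numpy semantics; gradients of broadcast operands are sum-reduced back
to the operand shape.

Only float64 data participates in graphs.  Anything wrapped via
:func:`as_tensor` with ``requires_grad=False`` acts as a constant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "maximum", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so it matches ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1.0)
            )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g @ np.swapaxes(other.data, -1, -2))
                if other.requires_grad:
                    other._accumulate(np.swapaxes(self.data, -1, -2) @ g)
            out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - val * val))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shape ops ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def backward(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape))
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int = -1, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = _make(out_val, (self,))
        if out.requires_grad:
            # ties split gradient equally among attaining entries
            mask = (self.data == val).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            def backward(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(g * mask)
            out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = _make(val, (self,))
        if out.requires_grad:
            def backward(g):
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accumulate(val * (g - dot))
            out._backward = backward
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = _make(np.swapaxes(self.data, a, b), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
            out._backward = backward
        return out


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=requires,
                  parents=tuple(p for p in parents if p.requires_grad))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = backward
    return out


def maximum(a, b) -> Tensor:
    """Elementwise max with subgradient: ties route gradient to ``a``."""
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out = _make(np.where(mask, a.data, b.data), (a, b))
    if out.requires_grad:
        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)
            if b.requires_grad:
                b._accumulate(g * ~mask)
        out._backward = backward
    return out


class Adam:
    """Adam with optional decoupled weight decay (AdamW when ``weight_decay>0``)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
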