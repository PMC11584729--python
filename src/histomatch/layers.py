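"""Neural building blocks (linear, layer norm, multi-head attention).

All layers hold their weights as :class:`~histomatch.autodiff.Tensor`
parameters and are initialized from an explicit ``numpy`` generator, so a
fixed seed reproduces the whole model bit for bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "LayerNorm", "MultiHeadAttention", "GatedMemory", "MLP"]


class Module:
    """Parameter container with recursive discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            p.data = np.array(state[k], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self._eps) ** -0.5 * self.gamma + self.beta


def _split_heads(x: Tensor, heads: int) -> Tensor:
    *batch, n, d = x.shape
    return x.reshape(*batch, n, heads, d // heads).swapaxes(-3, -2)


def _merge_heads(x: Tensor) -> Tensor:
    x = x.swapaxes(-3, -2)
    *batch, n, h, dh = x.shape
    return x.reshape(*batch, n, h * dh)


class MultiHeadAttention(Module):
    """Scaled-dot-product attention; covers both self and cross attention.

    ``residual`` adds the query input back (the self-attention configuration);
    cross-attention uses ``residual=False`` and no output projection, so with
    a single context token the output is exactly that token's value transform.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 residual: bool = True, out_proj: bool = True):
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng) if out_proj else None
        self._heads = heads
        self._residual = residual

    def forward(self, query: Tensor, context: Tensor) -> Tensor:
        if context.shape[-2] < 1:
            raise ValueError("attention context must contain at least one token")
        q = _split_heads(self.wq(query), self._heads)
        k = _split_heads(self.wk(context), self._heads)
        v = _split_heads(self.wv(context), self._heads)
        dh = q.shape[-1]
        scores = (q @ k.T) * (1.0 / np.sqrt(dh))
        attended = scores.softmax(axis=-1) @ v
        out = _merge_heads(attended)
        if self.wo is not None:
            out = self.wo(out)
        if self._residual:
            out = out + query
        return out


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


class GatedMemory(Module):
    """Sigmoid-gated feature refinement: x' = g*u + (1-g)*x.

    g = sigmoid(W_g [x; A] + b_g), u = tanh(W_u [x; A] + b_u), where A is the
    cross-attended context aligned with x.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.gate = Linear(2 * dim, dim, rng)
        self.candidate = Linear(2 * dim, dim, rng)

    def forward(self, x: Tensor, attended: Tensor) -> Tensor:
        joint = concat([x, attended], axis=-1)
        g = self.gate(joint).sigmoid()
        u = self.candidate(joint).tanh()
        return g * u + (1.0 - g) * x
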