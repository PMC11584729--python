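"""Pluggable image and text encoders with tiny desk-scale defaults.

The training loop only requires encoders honoring a shape contract —
an image encoder maps a 224x224 RGB canvas to ``m x d`` region features and
a text encoder maps a caption to ``L x d`` token features, deterministically
under fixed parameters.  The defaults shipped here are deliberately small
(two transformer blocks, d = 32) so the full joint objective runs on one
CPU in seconds; production-scale backbones (12-block ViT-768, 12-layer biomedical
BERT with partial freezing) satisfy the same contract and can be plugged in
through the registry.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .layers import Linear, LayerNorm, MLP, Module, MultiHeadAttention

__all__ = [
    "ImageTokens",
    "TextTokens",
    "TinyImageEncoder",
    "TinyTextEncoder",
    "ProjectionHead",
    "tokenize",
    "register_encoder",
    "get_encoder",
    "ENCODER_REGISTRY",
]


@dataclass
class ImageTokens:
    """Region features v_1..v_m for one view (an m x d matrix)."""

    features: Tensor
    source_id: str | None = None

    @property
    def m(self) -> int:
        return self.features.shape[-2]


@dataclass
class TextTokens:
    """Token features w_1..w_L for one caption (an L x d matrix)."""

    features: Tensor
    source_id: str | None = None

    @property
    def length(self) -> int:
        return self.features.shape[-2]


class _Block(Module):
    """Pre-norm transformer block: x + attn(LN x), then x + mlp(LN x)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng, residual=False)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, 2 * dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h)
        return x + self.mlp(self.norm2(x))


class TinyImageEncoder(Module):
    """Region-grid transformer for fixed-size canvases.

    The canvas is divided into a ``grid x grid`` array of regions; each
    region is block-mean pooled to a small raw descriptor, linearly embedded
    to ``d`` dimensions, combined with a learned region embedding and passed
    through ``n_blocks`` transformer blocks.  Output: ``m = grid**2`` region
    features of width ``d``.
    """

    def __init__(self, dim: int = 32, grid: int = 4, canvas_side: int = 224,
                 n_blocks: int = 2, heads: int = 2, pool: int = 8,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.canvas_side = canvas_side
        self.grid = grid
        self.pool = pool
        region = canvas_side // grid
        if region % pool != 0:
            raise ValueError("canvas_side/grid must be divisible by pool")
        raw_dim = (region // pool) ** 2 * 3
        self.embed = Linear(raw_dim, dim, rng)
        self.region_embedding = Tensor(
            rng.normal(0.0, 0.02, (grid * grid, dim)), requires_grad=True)
        self.blocks = [_Block(dim, heads, rng) for _ in range(n_blocks)]
        self.norm = LayerNorm(dim)
        self.dim = dim

    @property
    def m(self) -> int:
        return self.grid * self.grid

    def _raw_regions(self, canvas: np.ndarray) -> np.ndarray:
        s, p = self.canvas_side, self.pool
        if canvas.shape[-3:] != (s, s, 3):
            raise ValueError(f"expected {s}x{s}x3 canvas, got {canvas.shape}")
        x = canvas.astype(np.float64) / 255.0 - 0.5
        sp = s // p
        pooled = x.reshape(sp, p, sp, p, 3).mean(axis=(1, 3))  # (s/p, s/p, 3)
        r = sp // self.grid
        regions = (pooled
                   .reshape(self.grid, r, self.grid, r, 3)
                   .transpose(0, 2, 1, 3, 4)
                   .reshape(self.m, -1))
        return regions

    def forward(self, canvas: np.ndarray, source_id: str | None = None) -> ImageTokens:
        raw = Tensor(self._raw_regions(canvas))
        x = self.embed(raw) + self.region_embedding
        for block in self.blocks:
            x = block(x)
        return ImageTokens(features=self.norm(x), source_id=source_id)

    def forward_batch(self, canvases) -> Tensor:
        """Encode a stack of canvases in one graph; output (B, m, d)."""
        raw = Tensor(np.stack([self._raw_regions(c) for c in canvases]))
        x = self.embed(raw) + self.region_embedding
        for block in self.blocks:
            x = block(x)
        return self.norm(x)


_WORD_RE = re.compile(r"[a-z0-9]+")


def tokenize(caption: str, vocab_size: int, max_len: int) -> list[int]:
    """Deterministic hash-vocabulary tokenizer (md5-based, salt-free)."""
    if not caption or not caption.strip():
        raise ValueError("empty caption")
    words = _WORD_RE.findall(caption.lower())
    if not words:
        raise ValueError("caption contains no tokens")
    ids = [
        int.from_bytes(hashlib.md5(w.encode()).digest()[:4], "big") % vocab_size
        for w in words
    ]
    return ids[:max_len]


class TinyTextEncoder(Module):
    """Hash-vocabulary embedding plus a small transformer over tokens."""

    def __init__(self, dim: int = 32, vocab_size: int = 256, max_len: int = 16,
                 n_blocks: int = 1, heads: int = 2, seed: int = 1):
        rng = np.random.default_rng(seed)
        self.embedding = Tensor(rng.normal(0.0, 0.1, (vocab_size, dim)),
                                requires_grad=True)
        self.position = Tensor(rng.normal(0.0, 0.02, (max_len, dim)),
                               requires_grad=True)
        self.blocks = [_Block(dim, heads, rng) for _ in range(n_blocks)]
        self.norm = LayerNorm(dim)
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.dim = dim

    def forward(self, caption: str, source_id: str | None = None) -> TextTokens:
        ids = tokenize(caption, self.vocab_size, self.max_len)
        x = self.embedding[np.asarray(ids)] + self.position[: len(ids)]
        for block in self.blocks:
            x = block(x)
        return TextTokens(features=self.norm(x), source_id=source_id)


class ProjectionHead(Module):
    """Linear head mapping a pooled feature to distillation logits."""

    def __init__(self, dim: int = 32, out_dim: int = 32, seed: int = 2):
        rng = np.random.default_rng(seed)
        self.linear = Linear(dim, out_dim, rng)
        self.out_dim = out_dim

    def forward(self, pooled: Tensor) -> Tensor:
        if pooled.ndim == 1:
            pooled = pooled.reshape(1, -1)
            return self.linear(pooled).reshape(-1)
        return self.linear(pooled)


ENCODER_REGISTRY: dict[str, type] = {}


def register_encoder(name: str):
    def wrap(cls):
        ENCODER_REGISTRY[name] = cls
        return cls
    return wrap


register_encoder("tiny_image")(TinyImageEncoder)
register_encoder("tiny_text")(TinyTextEncoder)


def get_encoder(name: str, **kwargs):
    try:
        cls = ENCODER_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; registered: {sorted(ENCODER_REGISTRY)}")
    return cls(**kwargs)
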