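"""Iterative cross-attention image-text matching and its losses.

One image is a set of region features ``v_1..v_m``, one caption a set of
token features ``w_1..w_L``.  Matching runs for K steps: self-attention
highlights salient elements within each modality, cross-attention builds a
context ``A_k`` for each element from the other modality, a per-step
similarity mixes attended and global cosine terms with weight ``alpha``,
and a gated memory refines each modality's features before the next step.
The final similarity is the sum of per-step scores; a hinge ranking loss
over the in-batch similarity matrix pulls matched pairs above mismatched
ones by a margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .layers import GatedMemory, Module, MultiHeadAttention

__all__ = [
    "MatchConfig",
    "AttendedContext",
    "cosine_rows",
    "self_attend",
    "cross_attend",
    "gated_memory_refine",
    "step_similarity",
    "total_similarity",
    "ranking_loss",
    "total_loss",
    "MatchingModel",
]

_EPS = 1e-12  # zero-norm vectors get cosine similarity 0


@dataclass
class MatchConfig:
    alpha: float = 0.5          # weight of attended vs. global similarity terms
    steps: int = 2              # matching iterations K
    margin: float = 0.2         # hinge margin Delta
    heads: int = 2
    # negative aggregation: summed hinges give dense gradients at small batch
    # sizes; "hardest" (max-violation per anchor) suits large-batch training
    mode: str = "sum_all"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.steps < 1:
            raise ValueError("need at least one matching step")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.mode not in ("hardest", "sum_all"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AttendedContext:
    """Cross-attended contexts for one image-text pair at step k."""

    image: Tensor  # A_k^v, m x d — text-informed context per image region
    text: Tensor   # A_k^t, L x d — image-informed context per text token
    step: int = 0


def cosine_rows(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise cosine similarity between broadcastable (..., d) stacks."""
    a, b = as_tensor(a), as_tensor(b)
    dot = (a * b).sum(axis=-1)
    na = (a * a).sum(axis=-1) ** 0.5
    nb = (b * b).sum(axis=-1) ** 0.5
    return dot * ((na * nb + _EPS) ** -1.0)


def self_attend(x: Tensor, layer: MultiHeadAttention) -> Tensor:
    """Multi-head self-attention with residual; shape-preserving."""
    x = as_tensor(x)
    return layer(x, x)


def cross_attend(queries: Tensor, context: Tensor, layer: MultiHeadAttention,
                 step: int = 0) -> Tensor:
    """Attend each query element over the other modality's tokens.

    Each output row is a convex combination (per head) of context value
    vectors; with a single context token every row equals that token's
    value transform.
    """
    queries, context = as_tensor(queries), as_tensor(context)
    if context.shape[-2] < 1:
        raise ValueError("empty attention context")
    return layer(queries, context)


def gated_memory_refine(x: Tensor, attended: Tensor, gate: GatedMemory) -> Tensor:
    """Refine features with their cross-attended context via a sigmoid gate."""
    return gate(as_tensor(x), as_tensor(attended))


def _pooled(x: Tensor) -> Tensor:
    return x.mean(axis=-2, keepdims=True)


def step_similarity(v: Tensor, w: Tensor, attended_v: Tensor, attended_t: Tensor,
                    pooled_image: Tensor, pooled_text: Tensor,
                    alpha: float) -> Tensor:
    """Per-step similarity S_k between one image and one text.

    S_k = alpha * ( mean_i cos(v_i, A^v_i) + mean_j cos(A^t_j, w_j) )
        + (1-alpha) * ( mean_i cos(v_i, T) + mean_j cos(I, w_j) )

    Attended terms compare each element to its context from the other
    modality; global terms compare elements to the other modality's pooled
    vector.  Each mean runs over its own modality's element count (m image
    regions, L text tokens).
    """
    v, w = as_tensor(v), as_tensor(w)
    pooled_image = as_tensor(pooled_image)
    pooled_text = as_tensor(pooled_text)
    if pooled_image.ndim == 1:
        pooled_image = pooled_image.reshape(1, -1)
    if pooled_text.ndim == 1:
        pooled_text = pooled_text.reshape(1, -1)
    attended_term = (cosine_rows(v, attended_v).mean(axis=-1)
                     + cosine_rows(attended_t, w).mean(axis=-1))
    global_term = (cosine_rows(v, pooled_text).mean(axis=-1)
                   + cosine_rows(pooled_image, w).mean(axis=-1))
    return alpha * attended_term + (1.0 - alpha) * global_term


def total_similarity(step_scores) -> Tensor:
    """Final similarity S(I, T): plain sum of the K per-step scores."""
    scores = list(step_scores)
    if not scores:
        raise ValueError("need at least one step score")
    total = as_tensor(scores[0])
    for s in scores[1:]:
        total = total + as_tensor(s)
    return total


def ranking_loss(S, margin: float, mode: str = "hardest",
                 negative_mask: np.ndarray | None = None) -> Tensor:
    """Bidirectional hinge ranking loss over an n x n similarity matrix.

    Row i holds S(I_i, T_j).  For every negative pair j != i the hinge terms
    [margin - S_ii + S_ij]_+ (image anchor) and [margin - S_ii + S_ji]_+
    (text anchor) are formed; ``sum_all`` sums them all, ``hardest`` keeps
    only the largest violation per anchor.  ``negative_mask`` (True where a
    pair is a usable negative) lets callers exclude coincidental positives,
    e.g. two batch items sharing a caption.
    """
    S = as_tensor(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.all(np.isfinite(S.data)):
        raise ValueError("similarity matrix contains non-finite entries")
    n = S.shape[0]
    mask = ~np.eye(n, dtype=bool)
    if negative_mask is not None:
        mask = mask & np.asarray(negative_mask, dtype=bool)
    mask_f = Tensor(mask.astype(np.float64))
    diag = S[np.arange(n), np.arange(n)]
    image_anchor = ((margin - diag.reshape(n, 1)) + S).relu() * mask_f
    text_anchor = ((margin - diag.reshape(1, n)) + S).relu() * mask_f
    if mode == "sum_all":
        return image_anchor.sum() + text_anchor.sum()
    if mode == "hardest":
        return image_anchor.max(axis=1).sum() + text_anchor.max(axis=0).sum()
    raise ValueError(f"unknown mode {mode!r}")


def total_loss(l_ssl, l_cm, beta: float, gamma: float) -> Tensor:
    """Joint objective: beta * distillation loss + gamma * matching loss."""
    if beta < 0 or gamma < 0:
        raise ValueError("loss weights must be nonnegative")
    return beta * as_tensor(l_ssl) + gamma * as_tensor(l_cm)


class MatchingModel(Module):
    """The iterative matching head shared across all image-text pairs.

    Self-attention, cross-attention and gated-memory parameters are shared
    across the K steps; refinement carries features from step to step.
    """

    def __init__(self, dim: int = 32, config: MatchConfig | None = None,
                 seed: int = 3):
        rng = np.random.default_rng(seed)
        self.config = config or MatchConfig()
        heads = self.config.heads
        self.self_attn_image = MultiHeadAttention(dim, heads, rng, residual=True)
        self.self_attn_text = MultiHeadAttention(dim, heads, rng, residual=True)
        self.cross_image = MultiHeadAttention(dim, heads, rng,
                                              residual=False, out_proj=False)
        self.cross_text = MultiHeadAttention(dim, heads, rng,
                                             residual=False, out_proj=False)
        self.memory_image = GatedMemory(dim, rng)
        self.memory_text = GatedMemory(dim, rng)

    def pair_similarity(self, v: Tensor, w: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run K matching steps for one pair (or a batched stack of pairs).

        Accepts ``(m, d)`` / ``(L, d)`` token matrices, or ``(P, m, d)`` /
        ``(P, L, d)`` stacks scoring P pairs in one graph; returns
        ``(S, [S_1..S_K])`` with S scalar (or shape ``(P,)``).
        """
        cfg = self.config
        x_v, x_w = as_tensor(v), as_tensor(w)
        steps: list[Tensor] = []
        for k in range(cfg.steps):
            sv = self_attend(x_v, self.self_attn_image)
            sw = self_attend(x_w, self.self_attn_text)
            a_v = cross_attend(sv, sw, self.cross_image, step=k)
            a_t = cross_attend(sw, sv, self.cross_text, step=k)
            s_k = step_similarity(x_v, x_w, a_v, a_t,
                                  _pooled(x_v), _pooled(x_w), cfg.alpha)
            steps.append(s_k)
            if k + 1 < cfg.steps:
                x_v = gated_memory_refine(x_v, a_v, self.memory_image)
                x_w = gated_memory_refine(x_w, a_t, self.memory_text)
        return total_similarity(steps), steps

    def similarity_matrix(self, image_tokens, text_tokens) -> Tensor:
        """All-pairs similarity over a batch: entry (i, j) is S(I_i, T_j).

        When all images share one region count and all texts one token
        count, the n_i x n_t pairs are scored in a single batched graph;
        otherwise a per-pair loop is used.
        """
        image_tokens = [as_tensor(v) for v in image_tokens]
        text_tokens = [as_tensor(w) for w in text_tokens]
        n_i, n_t = len(image_tokens), len(text_tokens)
        uniform = (len({v.shape for v in image_tokens}) == 1
                   and len({w.shape for w in text_tokens}) == 1)
        if uniform:
            v_stack = concat([v.reshape(1, *v.shape) for v in image_tokens], axis=0)
            w_stack = concat([w.reshape(1, *w.shape) for w in text_tokens], axis=0)
            pair_v = v_stack[np.repeat(np.arange(n_i), n_t)]
            pair_w = w_stack[np.tile(np.arange(n_t), n_i)]
            s, _ = self.pair_similarity(pair_v, pair_w)
            return s.reshape(n_i, n_t)
        rows = []
        for v in image_tokens:
            cells = []
            for w in text_tokens:
                s, _ = self.pair_similarity(v, w)
                cells.append(s.reshape(1, 1))
            rows.append(concat(cells, axis=1))
        return concat(rows, axis=0)
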