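"""Teacher/student self-distillation: sharpening, cross-view loss, EMA.

The student is optimized so that, for every mild (teacher) view ``x`` and
every other view ``x'`` in the view set ``V``, the student's sharpened
distribution on ``x'`` matches the teacher's sharpened distribution on
``x``; the loss is the summed cross-entropy over those ordered pairs.  The
teacher is never touched by the optimizer: after each step its parameters
are moved toward the student's by an exponential moving average whose
momentum follows a cosine schedule from 0.996 to 1.0.  Centering of teacher
logits (a running mean subtracted before sharpening) guards against
collapse and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, maximum

__all__ = [
    "DistillConfig",
    "sharpen",
    "dino_loss",
    "ema_update",
    "momentum_schedule",
    "update_center",
]

LOG_CLAMP = 1e-12  # floor inside log() so zero student mass never yields -inf


@dataclass
class DistillConfig:
    student_temperature: float = 0.1
    teacher_temperature: float = 0.04
    center_momentum: float = 0.9
    lambda_start: float = 0.996
    lambda_end: float = 1.0
    total_steps: int = 1
    centering: bool = True

    def __post_init__(self):
        if self.student_temperature <= 0 or self.teacher_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if not (0.0 <= self.lambda_start <= self.lambda_end <= 1.0):
            raise ValueError("require 0 <= lambda_start <= lambda_end <= 1")


def sharpen(logits, temperature: float, center=None) -> Tensor:
    """Temperature-sharpened softmax, with optional center subtraction.

    The center (used on the teacher side) is subtracted before scaling.
    Returns a probability vector summing to one along the last axis.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = as_tensor(logits)
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("non-finite logits")
    if center is not None:
        logits = logits - as_tensor(center)
    return (logits * (1.0 / temperature)).softmax(axis=-1)


def dino_loss(teacher_probs, student_probs, teacher_indices=None) -> Tensor:
    """Cross-view distillation loss.

    ``teacher_probs`` are the sharpened teacher outputs for the mild views
    (constants — no gradient flows through them); ``student_probs`` holds one
    sharpened student distribution per view in V, aligned with the view set
    order.  ``teacher_indices`` maps each teacher distribution to its
    position in V so the ``x' != x`` exclusion can be applied; it defaults
    to the first ``len(teacher_probs)`` positions.
    """
    if teacher_indices is None:
        teacher_indices = tuple(range(len(teacher_probs)))
    if len(teacher_indices) != len(teacher_probs):
        raise ValueError("one index per teacher distribution required")
    total = None
    for p_t, ti in zip(teacher_probs, teacher_indices):
        p_t = np.asarray(p_t.data if isinstance(p_t, Tensor) else p_t, dtype=np.float64)
        for si, p_s in enumerate(student_probs):
            if si == ti:
                continue
            log_ps = maximum(as_tensor(p_s), LOG_CLAMP).log()
            term = -(Tensor(p_t) * log_ps).sum()
            total = term if total is None else total + term
    if total is None:
        raise ValueError("no teacher/student view pairs to distill")
    return total


def ema_update(theta_t, theta_s, lam: float):
    """Exponential moving average: theta_t' = lam*theta_t + (1-lam)*theta_s.

    Accepts parallel dicts of arrays (flat state dicts) or a pair of arrays.
    The teacher is only ever modified through this update, never by the
    optimizer.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if isinstance(theta_t, dict):
        if set(theta_t) != set(theta_s):
            raise ValueError("teacher/student parameter sets do not match")
        return {k: ema_update(theta_t[k], theta_s[k], lam) for k in theta_t}
    theta_t = np.asarray(theta_t, dtype=np.float64)
    theta_s = np.asarray(theta_s, dtype=np.float64)
    if theta_t.shape != theta_s.shape:
        raise ValueError("teacher/student parameter shapes do not match")
    return lam * theta_t + (1.0 - lam) * theta_s


def momentum_schedule(step: int, total: int, config: DistillConfig | None = None) -> float:
    """Cosine momentum schedule from ``lambda_start`` (0.996) to ``lambda_end`` (1).

    lambda(t) = end - (end - start) * (cos(pi*t/T) + 1) / 2; steps beyond T
    clamp to the end value.
    """
    if total < 1:
        raise ValueError("total steps must be >= 1")
    if step < 0:
        raise ValueError("step must be >= 0")
    config = config or DistillConfig()
    if step > total:
        return config.lambda_end
    span = config.lambda_end - config.lambda_start
    return config.lambda_end - span * (np.cos(np.pi * step / total) + 1.0) / 2.0


def update_center(center: np.ndarray, batch_mean: np.ndarray, momentum: float) -> np.ndarray:
    """Running center of teacher logits: c' = m*c + (1-m)*batch_mean."""
    center = np.asarray(center, dtype=np.float64)
    batch_mean = np.asarray(batch_mean, dtype=np.float64)
    if center.shape != batch_mean.shape:
        raise ValueError("center/batch mean shapes do not match")
    return momentum * center + (1.0 - momentum) * batch_mean
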