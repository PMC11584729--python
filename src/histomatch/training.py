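"""End-to-end training and embedding: the joint distillation + matching loop.

Each training step draws a batch of expanded patches with their captions,
builds a harmonized view set per patch, computes

* the cross-view distillation loss between teacher outputs on the two mild
  views and student outputs on all views, and
* the hinge ranking loss over the in-batch image-text similarity matrix
  produced by the iterative matching head,

combines them as ``beta * L_ssl + gamma * L_matching``, takes one optimizer
step on the student image encoder, text encoder, projection head and
matching head, and finally moves the teacher toward the student by EMA with
the cosine momentum schedule.  The teacher (image encoder + its head) is
never touched by the optimizer.

Defaults are desk scale: tiny encoders, batch 8, Adam at 1e-3.  The
production-scale learning rates (1e-6 / 5e-5) belong to large pretrained
backbones and live with the dataset presets of whoever plugs those in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .distillation import (DistillConfig, dino_loss, ema_update,
                           momentum_schedule, sharpen, update_center)
from .encoders import ProjectionHead, TinyImageEncoder, TinyTextEncoder
from .matching import MatchConfig, MatchingModel, ranking_loss, total_loss
from .slide_io import ExpandedPatch
from .views import ViewConfig, build_view_set, crossmodal_input_view

__all__ = [
    "RunConfig",
    "TrainStepReport",
    "JointModel",
    "Trainer",
    "plateau_lr",
    "PlateauScheduler",
    "embed_corpus",
]


@dataclass
class RunConfig:
    dim: int = 32
    expansion: int = 448
    batch_size: int = 8
    total_steps: int = 300
    learning_rate: float = 1e-3
    beta: float = 0.3               # weight of the distillation loss
    gamma: float = 1.0              # weight of the matching loss
    seed: int = 0
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    exclude_duplicate_captions: bool = True
    view: ViewConfig = field(default_factory=ViewConfig)
    distill: DistillConfig = field(default_factory=DistillConfig)
    match: MatchConfig = field(default_factory=MatchConfig)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2 (ranking loss needs negatives)")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau factor must lie in (0, 1)")


@dataclass
class TrainStepReport:
    step: int
    l_ssl: float
    l_cm: float
    l_total: float
    momentum: float

    def to_json(self) -> str:
        return json.dumps(vars(self))


class JointModel:
    """Student image encoder + teacher EMA copy + text encoder + matching head."""

    def __init__(self, config: RunConfig):
        self.config = config
        seed = config.seed
        self.student = TinyImageEncoder(dim=config.dim, seed=seed)
        self.head_student = ProjectionHead(dim=config.dim, out_dim=config.dim,
                                           seed=seed + 1)
        self.text = TinyTextEncoder(dim=config.dim, seed=seed + 2)
        self.matcher = MatchingModel(dim=config.dim, config=config.match,
                                     seed=seed + 3)
        # teacher starts as an exact copy of the student
        self.teacher = TinyImageEncoder(dim=config.dim, seed=seed)
        self.teacher.load_state_dict(self.student.state_dict())
        self.head_teacher = ProjectionHead(dim=config.dim, out_dim=config.dim,
                                           seed=seed + 1)
        self.head_teacher.load_state_dict(self.head_student.state_dict())
        self.center = np.zeros(config.dim)

    # -- parameter bookkeeping -----------------------------------------
    def trainable_parameters(self):
        return (self.student.parameters() + self.head_student.parameters()
                + self.text.parameters() + self.matcher.parameters())

    def teacher_state(self) -> dict[str, np.ndarray]:
        state = {f"enc.{k}": v for k, v in self.teacher.state_dict().items()}
        state |= {f"head.{k}": v for k, v in self.head_teacher.state_dict().items()}
        return state

    def student_state_for_teacher(self) -> dict[str, np.ndarray]:
        state = {f"enc.{k}": v for k, v in self.student.state_dict().items()}
        state |= {f"head.{k}": v for k, v in self.head_student.state_dict().items()}
        return state

    def load_teacher_state(self, state: dict[str, np.ndarray]):
        enc = {k[4:]: v for k, v in state.items() if k.startswith("enc.")}
        head = {k[5:]: v for k, v in state.items() if k.startswith("head.")}
        self.teacher.load_state_dict(enc)
        self.head_teacher.load_state_dict(head)

    # -- forward pieces -------------------------------------------------
    def student_logits(self, canvas: np.ndarray):
        tokens = self.student(canvas)
        pooled = tokens.features.mean(axis=0)
        return self.head_student(pooled)

    def teacher_logits(self, canvas: np.ndarray) -> np.ndarray:
        tokens = self.teacher(canvas)
        pooled = tokens.features.mean(axis=0)
        return self.head_teacher(pooled).data

    # -- checkpointing (flat npz; runtime artifact, not a repo file) ----
    def save(self, path, step: int = 0):
        arrays = {}
        for prefix, module in (("student", self.student),
                               ("head_student", self.head_student),
                               ("text", self.text),
                               ("matcher", self.matcher),
                               ("teacher", self.teacher),
                               ("head_teacher", self.head_teacher)):
            for k, v in module.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        arrays["center"] = self.center
        arrays["step"] = np.asarray(step)
        np.savez(path, **arrays)

    def load(self, path) -> int:
        with np.load(path) as data:
            for prefix, module in (("student", self.student),
                                   ("head_student", self.head_student),
                                   ("text", self.text),
                                   ("matcher", self.matcher),
                                   ("teacher", self.teacher),
                                   ("head_teacher", self.head_teacher)):
                state = {k.split("/", 1)[1]: data[k] for k in data.files
                         if k.startswith(prefix + "/")}
                module.load_state_dict(state)
            self.center = np.asarray(data["center"])
            return int(data["step"])


def plateau_lr(metric_history, lr: float, factor: float = 0.5,
               patience: int = 2) -> float:
    """Halve the learning rate after ``patience`` evaluations without
    improvement of the model-selection metric (R@sum, higher is better)."""
    history = [float(m) for m in metric_history]
    best = -np.inf
    waited = 0
    out = lr
    for m in history:
        if m > best:
            best = m
            waited = 0
        else:
            waited += 1
            if waited >= patience:
                out *= factor
                waited = 0
    return out


class PlateauScheduler:
    """Stateful wrapper around :func:`plateau_lr` driving an optimizer."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 2):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self._best = -np.inf
        self._waited = 0

    def step(self, metric: float):
        if metric > self._best:
            self._best = metric
            self._waited = 0
        else:
            self._waited += 1
            if self._waited >= self.patience:
                self.optimizer.lr *= self.factor
                self._waited = 0
        return self.optimizer.lr


class Trainer:
    """Runs the joint objective over (ExpandedPatch, caption) samples."""

    def __init__(self, model: JointModel, config: RunConfig | None = None):
        self.model = model
        self.config = config or model.config
        self.optimizer = Adam(model.trainable_parameters(),
                              lr=self.config.learning_rate)
        self.scheduler = PlateauScheduler(self.optimizer,
                                          self.config.plateau_factor,
                                          self.config.plateau_patience)
        self.rng = np.random.default_rng(self.config.seed)
        self.step_count = 0
        self.reports: list[TrainStepReport] = []

    def train_step(self, batch: list[tuple[ExpandedPatch, str]]) -> TrainStepReport:
        """One optimizer step on a batch of (expanded patch, caption) pairs."""
        if len(batch) < 2:
            raise ValueError("batch size must be >= 2 (no negative pairs otherwise)")
        cfg = self.config
        model = self.model

        # distillation branch: teacher sees the mild views, student all views
        vsets = [build_view_set(expanded, self.rng, cfg.view)
                 for expanded, _ in batch]
        n_views = len(vsets[0])
        student_canvases = [view.canvas for vset in vsets for view in vset.views]
        student_feats = model.student.forward_batch(student_canvases)
        student_logits = model.head_student(student_feats.mean(axis=-2))
        student_probs_all = sharpen(student_logits,
                                    cfg.distill.student_temperature)
        teacher_canvases = [vset.views[ti].canvas
                            for vset in vsets for ti in vset.teacher_indices]
        teacher_pooled = model.teacher.forward_batch(teacher_canvases).data.mean(axis=-2)
        teacher_logit_rows = model.head_teacher(Tensor(teacher_pooled)).data
        center = model.center if cfg.distill.centering else None
        teacher_probs_all = sharpen(teacher_logit_rows,
                                    cfg.distill.teacher_temperature, center).data
        l_ssl = None
        t_row = 0
        for b, vset in enumerate(vsets):
            teacher_probs = [teacher_probs_all[t_row + i]
                             for i in range(len(vset.teacher_indices))]
            t_row += len(vset.teacher_indices)
            student_probs = [student_probs_all[b * n_views + i]
                             for i in range(n_views)]
            term = dino_loss(teacher_probs, student_probs, vset.teacher_indices)
            l_ssl = term if l_ssl is None else l_ssl + term
        l_ssl = l_ssl * (1.0 / len(batch))

        # matching branch: one augmented input view + caption per pair
        input_canvases = [crossmodal_input_view(expanded, self.rng, train=True,
                                                config=cfg.view)
                          for expanded, _ in batch]
        batch_feats = model.student.forward_batch(input_canvases)
        image_tokens = [batch_feats[i] for i in range(len(batch))]
        captions = [caption for _, caption in batch]
        text_tokens = [model.text(caption).features for caption in captions]
        S = model.matcher.similarity_matrix(image_tokens, text_tokens)
        negative_mask = None
        if cfg.exclude_duplicate_captions:
            caps = np.asarray(captions, dtype=object)
            negative_mask = caps[:, None] != caps[None, :]
        l_cm = ranking_loss(S, cfg.match.margin, cfg.match.mode, negative_mask)

        loss = total_loss(l_ssl, l_cm, cfg.beta, cfg.gamma)
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.step()

        lam = momentum_schedule(self.step_count, cfg.total_steps, cfg.distill)
        model.load_teacher_state(ema_update(model.teacher_state(),
                                            model.student_state_for_teacher(),
                                            lam))
        if cfg.distill.centering and len(teacher_logit_rows):
            model.center = update_center(model.center,
                                         np.mean(teacher_logit_rows, axis=0),
                                         cfg.distill.center_momentum)
        self.step_count += 1
        report = TrainStepReport(step=self.step_count,
                                 l_ssl=float(l_ssl.data),
                                 l_cm=float(l_cm.data),
                                 l_total=float(loss.data),
                                 momentum=float(lam))
        self.reports.append(report)
        return report

    def fit(self, samples: list[tuple[ExpandedPatch, str]], steps: int,
            log_path: str | Path | None = None):
        """Train for ``steps`` batches drawn uniformly from ``samples``."""
        log_fh = open(log_path, "w") if log_path else None
        try:
            for _ in range(steps):
                idx = self.rng.choice(len(samples), size=self.config.batch_size,
                                      replace=len(samples) < self.config.batch_size)
                report = self.train_step([samples[i] for i in idx])
                if log_fh:
                    log_fh.write(report.to_json() + "\n")
        finally:
            if log_fh:
                log_fh.close()
        return self.reports


def embed_corpus(patches: list[ExpandedPatch], captions: list[str],
                 model: JointModel) -> np.ndarray:
    """Deterministic eval-time score table: every patch x every caption.

    Uses center crops with no augmentation; entry (i, j) is the summed
    K-step similarity S(I_i, T_j), bounded by 2K in magnitude.
    """
    if not patches or not captions:
        raise ValueError("need at least one patch and one caption")
    text_features = [model.text(c).features for c in captions]
    canvases = [crossmodal_input_view(p, train=False, config=model.config.view)
                for p in patches]
    feats = model.student.forward_batch(canvases)
    image_tokens = [feats[i] for i in range(len(patches))]
    return model.matcher.similarity_matrix(image_tokens, text_features).data.copy()
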