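"""Desk-scale experiment driver: synthetic corpus -> training -> retrieval.

This wires the whole stack together at sizes that run on one CPU in a few
minutes: a small class-balanced synthetic corpus, tissue masking and patch
enumeration, expanded-patch extraction, joint distillation + matching
training with tiny encoders, and the full retrieval evaluation (patch-level
bidirectional R@K, slide-level majority voting and Recall@K@V).

Slides are split between train and test at the slide level so no test
patch's slide contributes to training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import evaluate_retrieval
from .slide_io import (ExpandedPatch, compute_tissue_mask, enumerate_patches,
                       make_thumbnail, read_region)
from .synthetic import SyntheticCorpus, build_corpus
from .training import JointModel, RunConfig, Trainer, embed_corpus

__all__ = ["ExperimentConfig", "corpus_patches", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Conditions for the end-to-end synthetic retrieval experiment."""

    n_classes: int = 4
    slides_per_class: int = 6
    test_slides_per_class: int = 2
    side_px: int = 640
    base_size: int = 448
    expansion: int = 448
    stride: int = 192
    min_tissue_fraction: float = 0.02
    steps: int = 300
    seed: int = 0
    ks: tuple[int, ...] = (1, 3, 5, 10)
    voting_v: int = 5
    run: RunConfig = field(default_factory=RunConfig)


@dataclass
class PatchRecord:
    expanded: ExpandedPatch
    caption: str
    class_id: int
    slide_id: str


def corpus_patches(corpus: SyntheticCorpus, base_size: int = 448,
                   expansion: int = 448, stride: int = 192,
                   min_tissue_fraction: float = 0.02,
                   mask_downsample: int = 16) -> list[PatchRecord]:
    """Enumerate tissue patches of every corpus slide as expanded patches."""
    records: list[PatchRecord] = []
    caption_by_slide = dict(zip(corpus.manifest["slide_id"],
                                corpus.manifest["caption"]))
    class_by_slide = dict(zip(corpus.manifest["slide_id"],
                              corpus.manifest["class_id"]))
    for slide_id, slide in corpus.slides.items():
        thumb = make_thumbnail(slide, mask_downsample)
        mask = compute_tissue_mask(thumb, downsample=mask_downsample,
                                   slide_shape=slide.shape)
        for spec in enumerate_patches(mask, base_size, stride,
                                      min_tissue_fraction, slide_id=slide_id):
            records.append(PatchRecord(
                expanded=read_region(slide, spec, expansion),
                caption=caption_by_slide[slide_id],
                class_id=int(class_by_slide[slide_id]),
                slide_id=slide_id,
            ))
    return records


def _split_slides(corpus: SyntheticCorpus, test_per_class: int,
                  rng: np.random.Generator) -> tuple[set, set]:
    test: set = set()
    for class_id, group in corpus.manifest.groupby("class_id"):
        ids = sorted(group["slide_id"])
        picked = rng.choice(len(ids), size=test_per_class, replace=False)
        test.update(ids[i] for i in picked)
    train = set(corpus.manifest["slide_id"]) - test
    return train, test


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Run the full synthetic retrieval experiment; returns a report dict.

    The report carries the evaluation-layer output (recall tables, R@sum,
    majority voting, Recall@K@V, confusion matrices), the per-step training
    reports, and the raw test-set similarity table.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)
    corpus = build_corpus(config.n_classes, config.slides_per_class,
                          config.side_px, seed=config.seed)
    records = corpus_patches(corpus, config.base_size, config.expansion,
                             config.stride, config.min_tissue_fraction)
    train_slides, test_slides = _split_slides(corpus,
                                              config.test_slides_per_class, rng)
    train_records = [r for r in records if r.slide_id in train_slides]
    test_records = [r for r in records if r.slide_id in test_slides]
    if not train_records or not test_records:
        raise RuntimeError("tissue masking produced an empty split")

    run_cfg = config.run
    run_cfg.seed = config.seed
    run_cfg.total_steps = config.steps
    model = JointModel(run_cfg)
    trainer = Trainer(model, run_cfg)
    samples = [(r.expanded, r.caption) for r in train_records]
    trainer.fit(samples, config.steps)

    captions = corpus.captions
    similarity = embed_corpus([r.expanded for r in test_records], captions, model)
    report = evaluate_retrieval(
        similarity,
        np.asarray([r.class_id for r in test_records]),
        [r.slide_id for r in test_records],
        [s.name for s in corpus.class_specs],
        ks=config.ks,
        voting_v=config.voting_v,
    )
    report["train_reports"] = trainer.reports
    report["similarity"] = similarity
    report["n_train_patches"] = len(train_records)
    report["n_test_patches"] = len(test_records)
    report["model"] = model
    return report
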