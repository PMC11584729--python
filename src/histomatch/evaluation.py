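"""Retrieval metrics and slide-level aggregation.

Patch-level metrics are the usual bidirectional recalls: R@K is the
percentage of queries whose true match appears in the top K retrieved
candidates, and R@sum is the plain sum of the reported R@K values across K
levels and directions.  Slide-level metrics aggregate the patches of a
whole-slide image: plain majority voting over per-patch labels, and the
weighted voting metric Recall@K@V, in which each patch contributes its top
V diagnoses weighted by normalized similarity scores, diagnoses are
aggregated across the slide's patches, and the slide counts as a success
when its true diagnosis lands in the top K of that aggregate ranking.

All ordering is deterministic: descending score, ties broken by ascending
candidate index; vote ties break on highest summed score, then lowest
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "RecallTable",
    "WSIVote",
    "ConfusionMatrix",
    "rank_candidates",
    "recall_at_k",
    "r_at_sum",
    "patch_label",
    "wsi_majority_vote",
    "recall_at_k_at_v",
    "confusion_matrix_at_k",
    "evaluate_retrieval",
]


@dataclass
class RankedList:
    query_id: str
    candidates: list
    scores: np.ndarray

    def top(self, k: int) -> list:
        return self.candidates[:k]


@dataclass
class RecallTable:
    direction: str                     # "text_retrieval" | "image_retrieval"
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        ks = sorted(self.values)
        vals = [self.values[k] for k in ks]
        if any(not (0.0 <= v <= 100.0) for v in vals):
            raise ValueError("recall values must lie in [0, 100]")
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("recall must be nondecreasing in K")


@dataclass
class WSIVote:
    slide_id: str
    ranking: list           # aggregated diagnosis ranking, best first
    scores: np.ndarray      # aggregate weight per diagnosis (class order)
    voting_threshold: int
    recall_level: int
    success: bool


@dataclass
class ConfusionMatrix:
    counts: np.ndarray      # rows = true class, columns = assigned class
    classes: list

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.counts.sum(), 1))


def rank_candidates(scores, candidates=None, query_id: str = "") -> RankedList:
    """Order candidates by descending score; ties by ascending index."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 1:
        raise ValueError("need at least one candidate")
    if np.isnan(scores).any():
        raise ValueError("NaN score")
    if candidates is None:
        candidates = list(range(scores.size))
    order = np.argsort(-scores, kind="stable")
    return RankedList(query_id=query_id,
                      candidates=[candidates[i] for i in order],
                      scores=scores[order])


def recall_at_k(ranked_lists, truths, k: int) -> float:
    """Percentage of queries whose truth appears within the top K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    ranked_lists = list(ranked_lists)
    truths = list(truths)
    if len(ranked_lists) != len(truths):
        raise ValueError("one truth per query required")
    hits = sum(truth in ranked.top(k) for ranked, truth in zip(ranked_lists, truths))
    return 100.0 * hits / len(ranked_lists)


def r_at_sum(recall_values) -> float:
    """Sum of reported per-direction recall percentages (the R@sum column)."""
    values = [float(v) for v in recall_values]
    if any(not (0.0 <= v <= 100.0) for v in values):
        raise ValueError("recall values must lie in [0, 100]")
    return float(sum(values))


def patch_label(ranked_diagnoses, true_diagnosis, k: int):
    """Label a patch from its retrieved diagnosis ranking at level K.

    The patch keeps its true diagnosis when it appears among the top K
    retrieved diagnoses; otherwise it is assigned the rank-1 diagnosis.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    ranked_diagnoses = list(ranked_diagnoses)
    if not ranked_diagnoses:
        raise ValueError("empty diagnosis ranking")
    if true_diagnosis in ranked_diagnoses[:k]:
        return true_diagnosis
    return ranked_diagnoses[0]


def wsi_majority_vote(labels, scores=None):
    """Most common patch label for a slide.

    Ties break on the highest summed patch score among tied labels (when
    scores are given), then on the lowest label under ascending sort order.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("slide has no patches")
    counts: dict = {}
    sums: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        if scores is not None:
            sums[lab] = sums.get(lab, 0.0) + float(scores[i])
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) > 1 and scores is not None:
        best = max(sums[lab] for lab in tied)
        tied = [lab for lab in tied if sums[lab] == best]
    return sorted(tied)[0]


def recall_at_k_at_v(patch_scores, voting_threshold: int, k: int,
                     true_index: int, classes=None,
                     normalize: str = "linear",
                     slide_id: str = "") -> WSIVote:
    """Weighted-voting slide metric Recall@K@V.

    ``patch_scores`` is an ``n_patches x C`` array of per-diagnosis scores.
    Per patch the C scores are normalized to sum to one ("linear", the
    default, requires strictly positive input; "softmax" accepts any real
    scores), all but the top V entries are zeroed, and the masked weights
    are summed across patches.  Diagnoses are ranked by that aggregate and
    the slide succeeds when the true diagnosis sits within the top K.
    """
    scores = np.asarray(patch_scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[None, :]
    n_patches, n_classes = scores.shape
    if not (1 <= voting_threshold <= n_classes):
        raise ValueError("voting threshold must lie in [1, C]")
    if not (1 <= k <= n_classes):
        raise ValueError("K must lie in [1, C]")
    if not (0 <= true_index < n_classes):
        raise ValueError("true diagnosis index out of range")
    if normalize == "linear":
        if (scores <= 0).any():
            raise ValueError("linear normalization requires positive scores")
        probs = scores / scores.sum(axis=1, keepdims=True)
    elif normalize == "softmax":
        shifted = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    aggregate = np.zeros(n_classes)
    for row in probs:
        order = np.argsort(-row, kind="stable")[:voting_threshold]
        masked = np.zeros(n_classes)
        masked[order] = row[order]
        aggregate += masked
    ranked = rank_candidates(aggregate,
                             candidates=list(classes) if classes is not None
                             else list(range(n_classes)),
                             query_id=slide_id)
    truth = (list(classes)[true_index] if classes is not None else true_index)
    return WSIVote(slide_id=slide_id, ranking=ranked.candidates,
                   scores=aggregate, voting_threshold=voting_threshold,
                   recall_level=k, success=truth in ranked.top(k))


def confusion_matrix_at_k(assigned, truths, classes) -> ConfusionMatrix:
    """Count matrix with rows = true diagnosis, columns = assigned."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    assigned, truths = list(assigned), list(truths)
    if len(assigned) != len(truths):
        raise ValueError("assigned/truth lengths differ")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, t in zip(assigned, truths):
        if a not in index or t not in index:
            raise ValueError(f"label outside class list: {a!r}/{t!r}")
        counts[index[t], index[a]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def evaluate_retrieval(similarity: np.ndarray, patch_class: np.ndarray,
                       slide_ids, class_names,
                       ks=(1, 3, 5, 10), voting_v: int = 5,
                       normalize: str = "softmax") -> dict:
    """Full evaluation driver over a patch x class-caption similarity table.

    ``similarity[i, c]`` scores patch i against the caption of class c;
    ``patch_class[i]`` is the true class index.  Computes patch-level text
    retrieval R@K (each patch queries the C captions), image retrieval R@K
    (each caption queries all patches; success when a top-K patch carries
    the class), R@sum over both directions, slide-level majority-vote R@K,
    confusion matrices at each K, and Recall@K@V with the given V.
    """
    similarity = np.asarray(similarity, dtype=np.float64)
    patch_class = np.asarray(patch_class)
    slide_ids = np.asarray(slide_ids)
    class_names = list(class_names)
    n_patches, n_classes = similarity.shape
    ks = [k for k in ks if k <= n_classes] or [min(ks)]

    patch_rankings = [rank_candidates(similarity[i], candidates=class_names,
                                      query_id=f"patch{i}")
                      for i in range(n_patches)]
    truths = [class_names[c] for c in patch_class]
    text_recall = RecallTable("text_retrieval", {
        k: recall_at_k(patch_rankings, truths, k) for k in ks})

    image_hits = {k: 0 for k in ks}
    for c in range(n_classes):
        ranked = rank_candidates(similarity[:, c], query_id=class_names[c])
        for k in ks:
            if any(patch_class[i] == c for i in ranked.top(k)):
                image_hits[k] += 1
    image_recall = RecallTable("image_retrieval", {
        k: 100.0 * image_hits[k] / n_classes for k in ks})

    rsum = r_at_sum(list(text_recall.values.values())
                    + list(image_recall.values.values()))

    report = {
        "text_retrieval": text_recall,
        "image_retrieval": image_recall,
        "r_at_sum": rsum,
        "wsi_majority": {},
        "recall_at_k_at_v": {},
        "confusion": {},
    }

    unique_slides = list(dict.fromkeys(slide_ids.tolist()))
    slide_truth = {s: class_names[patch_class[slide_ids == s][0]]
                   for s in unique_slides}
    for k in ks:
        labels = [patch_label(patch_rankings[i].candidates, truths[i], k)
                  for i in range(n_patches)]
        report["confusion"][k] = confusion_matrix_at_k(labels, truths, class_names)
        voted, votes_v = {}, {}
        for s in unique_slides:
            idx = np.where(slide_ids == s)[0]
            voted[s] = wsi_majority_vote([labels[i] for i in idx],
                                         [similarity[i].max() for i in idx])
            vote = recall_at_k_at_v(similarity[idx], min(voting_v, n_classes), k,
                                    int(patch_class[idx[0]]), classes=class_names,
                                    normalize=normalize, slide_id=str(s))
            votes_v[s] = vote.success
        report["wsi_majority"][k] = 100.0 * np.mean(
            [voted[s] == slide_truth[s] for s in unique_slides])
        report["recall_at_k_at_v"][k] = 100.0 * np.mean(
            [votes_v[s] for s in unique_slides])
    return report
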