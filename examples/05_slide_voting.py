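"""Slide-level aggregation: majority voting and weighted Recall@K@V.

Uses a hand-built per-patch score table for one slide over four diagnoses
to show how the two aggregation rules differ: plain majority voting counts
patch labels, while Recall@K@V sums each patch's top-V normalized scores,
so confident patches weigh more.
"""

import numpy as np

from histomatch.evaluation import (patch_label, rank_candidates,
                                   recall_at_k_at_v, wsi_majority_vote)

classes = ["ductal", "lobular", "mucinous", "papillary"]
truth = "ductal"
# three patches; the second one is confidently wrong
patch_scores = np.array([
    [0.40, 0.35, 0.15, 0.10],
    [0.20, 0.60, 0.10, 0.10],
    [0.45, 0.15, 0.30, 0.10],
])

labels = []
for row in patch_scores:
    ranked = rank_candidates(row, candidates=classes)
    labels.append(patch_label(ranked.candidates, truth, k=1))
print("patch labels at K=1:", labels)
print("majority vote:", wsi_majority_vote(labels, patch_scores.max(axis=1)))

for v in (1, 2, 4):
    vote = recall_at_k_at_v(patch_scores, voting_threshold=v, k=1,
                            true_index=0, classes=classes)
    print(f"Recall@1@V={v}: ranking {vote.ranking}, "
          f"weights {np.round(vote.scores, 2).tolist()}, success={vote.success}")
# At V=1 only each patch's top diagnosis votes; widening V lets runner-up
# scores contribute until over-inclusion starts diluting the signal.
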