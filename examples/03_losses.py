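"""The two halves of the training objective on worked numbers.

Distillation: cross-view loss over a view set of 8 with 2 teacher views —
uniform distributions give exactly 14 * ln(C); one-hot agreement gives 0.
Matching: the bidirectional hinge ranking loss on a tiny similarity matrix,
and the cosine momentum schedule for the teacher EMA.
"""

import numpy as np

from histomatch.autodiff import Tensor
from histomatch.distillation import dino_loss, momentum_schedule
from histomatch.matching import ranking_loss, total_loss

C = 4
uniform = np.full(C, 1 / C)
loss_u = float(dino_loss([uniform] * 2, [Tensor(uniform)] * 8).data)
print(f"uniform distillation loss (|V|=8, C=4): {loss_u:.4f}"
      f"  (= 14 ln 4 = {14 * np.log(4):.4f})")

onehot = np.eye(C)[1]
loss_0 = float(dino_loss([onehot] * 2, [Tensor(onehot)] * 8).data)
print(f"one-hot agreement loss: {loss_0:.4f}  (perfect student/teacher match)")

S = np.array([[0.5, 0.6], [0.7, 0.8]])
hinge = float(ranking_loss(S, margin=0.2, mode="sum_all").data)
print(f"ranking loss on S={S.tolist()}, margin 0.2: {hinge:.2f}"
      "  (0.3 + 0.4 + 0.1 + 0.0 over the four anchor/negative terms)")

joint = float(total_loss(2.0, 1.0, beta=0.3, gamma=1.0).data)
print(f"joint loss at beta=0.3, gamma=1: {joint:.2f}")

for t, T in [(0, 1000), (500, 1000), (1000, 1000)]:
    print(f"momentum schedule lambda(t={t}, T={T}) = {momentum_schedule(t, T):.4f}")
# lambda rises 0.996 -> 1.0 on a half-cosine: the teacher tracks the
# student closely early in training and freezes toward the end.
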