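# Methods

## Problem setting

Digital pathology archives pair gigapixel whole-slide images (WSIs) with
text — a primary diagnosis or a free-text report. Cross-modal retrieval
maps both modalities into a common space so that a patch can retrieve its
diagnosis text and a text query can retrieve matching tissue. Labeled
pathology data is scarce, so the image representation is learned with
self-supervision; the difficulty specific to WSIs is that standard
multi-crop self-distillation rescales its local crops, which changes the
apparent magnification of tissue and destroys scale semantics that
pathology features depend on.

`histomatch` implements the full pipeline: scale-harmonized multi-crop
view generation, teacher/student self-distillation, an iterative
cross-attention matching head with a hinge ranking loss, and the retrieval
metrics used to evaluate slide-level diagnosis search.

## Scale-harmonized views

Patches are read from the slide at a side *larger* than the network input
(the *expanded patch*, default 448 px at a 20X-equivalent magnification;
300 px is the preset for smaller-patch corpora). From the expanded patch,
crops are taken at native scale — never interpolated:

* **local views**: crop side drawn uniformly from [50, 140);
* **global views**: crop side drawn uniformly from [140, 224], truncated
  to the expanded side when it is below 224.

Each crop is optionally flipped (p = 0.5 per axis), color-jittered, and
placed centered on a black 224×224 canvas. The *harmonization invariant* —
with photometric augmentation disabled, the pad window of every view is
bit-identical to a flipped sub-array of the expanded patch — is asserted
in the test suite at the bit level.

The default view set V holds 8 views: 2 *mild*-augmented global views
(consumed by the teacher) and 6 *hyper*-augmented local views; the student
consumes all 8. The pairing of global↔teacher/mild and
local↔student/hyper follows the usual multi-crop convention and is
configurable, as is the number of views. Jitter magnitudes
(brightness/contrast/saturation/hue) are mild = (0.1, 0.1, 0.05, 0.02) and
hyper = (0.4, 0.4, 0.2, 0.1) — chosen so the mild regime is barely
perceptible and the hyper regime clearly distorts color without destroying
hue identity.

Boundary policy: when the symmetric expansion of a patch overflows the
slide, the expanded box is shifted inward. Padding with synthetic pixels
happens only at the view-canvas stage, never at slide reads.

## Tissue masking and patch enumeration

A thumbnail (block-mean, downsample ≤ 32) pixel is tissue when grayscale
luminance < 0.8 (0–1 scale) and HSV saturation > 0.05 — a deterministic
rule separating stained tissue from white glass. Candidate patches are
enumerated row-major on a stride grid and kept when their mask fraction
clears `min_tissue_fraction`. The default threshold is 0.02: block-mean
thumbnails dilute sparse texture toward the background color, so the
mask systematically underestimates the tissue fraction, and a permissive
threshold keeps sparsely textured (low blob-density) synthetic classes
represented. These are artifact-level plumbing choices; the retrieval
method does not depend on them.

## Distillation objective

Student and teacher share one architecture with parameters θ_s, θ_t. For
logits z, `sharpen(z, τ, c)` = softmax((z − c)/τ); the teacher side uses
τ_t = 0.04 and subtracts a running center c (momentum 0.9) before
sharpening, the student uses τ_s = 0.1 without centering. The loss sums,
over the two teacher (mild) views x and every other view x′ ∈ V, the
cross-entropies −Σ P_t(x)·log P_s(x′). With |V| = 8 that is 14 ordered
pairs, so uniform distributions over C classes give exactly 14·ln C — a
closed form the tests pin. log is clamped at 10⁻¹² so a collapsed student
distribution can never produce −∞.

The optimizer never touches the teacher. After each step,
θ_t ← λθ_t + (1−λ)θ_s elementwise, with λ on a half-cosine from 0.996 at
step 0 to 1.0 at the final step (clamped beyond). Temperatures and
centering are configurable and centering can be disabled, which reduces
the objective to its bare cross-view form.

## Iterative cross-modal matching

One image is m region features v₁..v_m, one caption L token features
w₁..w_L. Matching runs K = 2 steps (configurable). Per step k:

1. self-attention (multi-head, residual) within each modality;
2. cross-attention builds a context A_k^v per region (attending over text
   tokens) and A_k^t per token (attending over regions);
3. the step similarity mixes attended and global cosine terms with weight
   α = 0.5:

       S_k = α(mean_i cos(v_i, A_k^v_i) + mean_j cos(A_k^t_j, w_j))
           + (1−α)(mean_i cos(v_i, T) + mean_j cos(I, w_j))

   where I and T are the mean-pooled image and text vectors. Means run
   over each modality's own element count (m and L). Zero-norm vectors get
   cosine 0 rather than NaN;
4. a gated memory refines features for the next step:
   x′ = g⊙u + (1−g)⊙x with g = σ(W_g[x; A] + b_g), u = tanh(W_u[x; A] + b_u).
   The sigmoid-gated candidate update is this package's concrete choice
   for the memory; the literature this head descends from leaves the
   equations to its backbone reference.

The final similarity is S = Σ_k S_k, bounded by 2K in magnitude. Over a
batch of n pairs the similarity matrix S_ij = S(I_i, T_j) feeds a
bidirectional hinge ranking loss with margin Δ = 0.2: for each anchor,
terms [Δ − S_ii + S_ij]₊ (image anchor) and [Δ − S_ii + S_ji]₊ (text
anchor) over negatives j ≠ i.

**Negative aggregation.** Two aggregations are implemented: summing all
hinge terms (`sum_all`, the default) and keeping only the hardest
violation per anchor (`hardest`). Hardest-negative mining is the right
choice for large-batch training, but at desk scale (batch 8, few classes)
each anchor sees at most a handful of usable negatives and the max
operator passes gradient through only one of them; in the package's own
end-to-end experiments summed hinges trained reliably while hardest-negative
stalled below the target recall. Both stay available in `MatchConfig`.

When a batch contains two pairs with the same caption (unavoidable when
captions are class-level diagnoses), treating one as the other's negative
is contradictory; the training driver therefore masks same-caption
"negatives" out of the loss (configurable).

The joint objective is L = β·L_ssl + γ·L_matching. β = 0.3, γ = 1 is the
default (the breast-archive preset); 0.5/1 and 0.4/1 are the presets for
the gastric and lung/colon corpora.

## Encoders

Training requires only a shape contract: image canvas → m×d region
features, caption → L×d token features, deterministic under fixed
parameters. The shipped defaults are deliberately tiny so the whole
objective runs on one CPU: the image encoder mean-pools the canvas into a
4×4 region grid of raw color descriptors, embeds them to d = 32 and
applies two pre-norm transformer blocks; the text encoder hashes words
(md5, salt-free) into a 256-slot embedding table with learned positions
and one transformer block. Production-scale backbones (12-block ViT-768, a
12-layer biomedical BERT, partial freezing) satisfy the same contract and
can be registered by name; EMA then applies to all teacher parameters,
frozen ones included (they simply never change). Distillation is
image-side only; the text encoder has no teacher.

All differentiable components run on a minimal in-repo reverse-mode
autodiff core (`histomatch.autodiff`) over numpy arrays — some thirty
primitives with broadcasting-aware gradients, verified against central
differences in the test suite — plus an Adam/AdamW optimizer.

## Retrieval metrics

* **R@K**: percentage of queries whose true match is within the top K;
  ties in candidate scores break by ascending candidate index,
  deterministically. **R@sum** is the plain sum of reported R@K values
  over both directions and all K levels.
* **Patch label rule** (level K): a patch keeps its true diagnosis if it
  appears in its top-K retrieved diagnoses, else it takes the rank-1
  diagnosis. **WSI majority voting** assigns each slide its modal patch
  label; ties break by the highest summed patch score, then lowest label.
* **Recall@K@V**: per patch, the C diagnosis scores are normalized to sum
  to one, all but the top V are zeroed, and the masked weights are summed
  across the slide's patches; the slide succeeds when its true diagnosis
  ranks in the top K of the aggregate. Linear normalization (divide by the
  sum) is the default and requires positive scores; a softmax alternative
  accepts raw similarities, which lie in [−2K, 2K], and is what the
  evaluation driver uses on raw similarity tables.
* **Confusion matrices** at each K from the assigned labels (rows = true).
* Text→WSI retrieval is represented as an explicitly unsupported
  direction (all patches of a slide share one diagnosis), not as zeros.

## Synthetic corpus

The generator emulates the *pairing structure* of a slide archive, not
histology: each class has a base hue (evenly spaced on the hue circle), a
blob density (1–3 per 10⁴ px²), a radius range, and a templated diagnosis
caption; slides are white canvases with hue-coded elliptical blobs.
Regeneration under one seed is byte-identical. Classes are separable by
hue alone — a mean-hue nearest-class rule exceeds 90% patch accuracy in
the tests — so the end-to-end task is winnable by construction. What
passing tests therefore show is that the geometry, objectives, training
loop and metrics are implemented correctly and can align a learnable
signal across modalities; they say nothing about performance on real
stained tissue, stain variation, scanner artifacts or pyramid levels,
which the generator deliberately does not model.

## Desk-scale experiment conditions

The end-to-end experiment (`histomatch.pipeline.run_experiment`, also run
by `scripts/acceptance.py`) uses: 4 classes × 6 slides of 640² px, 448-px
expanded patches on a 192-px stride (4 per slide), a slide-level split of
4 train / 2 test slides per class, tiny encoders (d = 32, m = 16), batch
8, Adam at 10⁻³, and 300 training steps — sizes chosen so the whole run
finishes in a few minutes on one CPU while leaving enough test patches
(32) and slides (8) for stable percentages. The production-scale learning
rates (10⁻⁶, 5×10⁻⁵) belong to large pretrained backbones and live with
dataset presets. R@sum on a held-out split is the model-selection metric;
a plateau scheduler halves the learning rate after `patience` evaluations
without improvement.

## Numerical choices and edge cases

* Cosine denominators carry an additive 10⁻¹² so zero-norm vectors yield
  similarity 0 rather than NaN.
* `max`-reduction gradients split equally among tied maxima; hinge terms
  route tie gradients to the first operand.
* Softmax is computed with max-subtraction; sharpening validates
  finiteness of logits and positivity of temperatures.
* Candidate ordering everywhere is stable descending sort (ties →
  ascending index); vote ties → score sum → lowest label.
* An all-background slide yields zero patches (not an error); an empty
  train/test split aborts the experiment with a clear error.
* EMA momentum outside [0, 1], mismatched parameter shapes, non-square
  similarity matrices, empty captions and out-of-bounds crops all raise
  `ValueError` rather than propagating silently.

## Known limitations

* The tiny encoders have no pretraining and a color-dominated receptive
  field; they are contract-compliant stand-ins for pathology-scale
  backbones, adequate for the synthetic task only.
* Pyramidal WSI formats are supported only through the raster adapter
  surface; no native multi-resolution reads.
* Whether a text-side teacher would help is untested here (image-only
  distillation by design).
* The similarity "matrix" is square but not constrained symmetric;
  S(I_i, T_j) ≠ S(I_j, T_i) in general.
* Statistical comparisons between methods (significance tests) and
  plotting are out of scope.
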