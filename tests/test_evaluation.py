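"""Retrieval metrics vs. counting/membership/aggregation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histomatch.evaluation import (RankedList, confusion_matrix_at_k,
                                   patch_label, r_at_sum, rank_candidates,
                                   recall_at_k, recall_at_k_at_v,
                                   wsi_majority_vote)


class TestRankCandidates:
    def test_descending_order(self):
        ranked = rank_candidates([0.1, 0.9, 0.5])
        assert ranked.candidates == [1, 2, 0]

    def test_ties_break_by_index(self):
        ranked = rank_candidates([0.5, 0.5, 0.5])
        assert ranked.candidates == [0, 1, 2]

    def test_matches_sort_oracle(self, rng):
        for _ in range(50):
            scores = rng.normal(size=10)
            ranked = rank_candidates(scores)
            oracle = sorted(range(10), key=lambda i: (-scores[i], i))
            assert ranked.candidates == oracle
            assert (np.diff(ranked.scores) <= 0).all()

    def test_nan_errors(self):
        with pytest.raises(ValueError):
            rank_candidates([0.1, np.nan])


class TestRecallAtK:
    def test_single_query_rank_three(self):
        ranked = [RankedList("q", ["b", "c", "a", "d"], np.arange(4.0)[::-1])]
        assert recall_at_k(ranked, ["a"], 1) == 0.0
        assert recall_at_k(ranked, ["a"], 3) == 100.0
        assert recall_at_k(ranked, ["a"], 5) == 100.0

    def test_all_rank_one(self):
        ranked = [RankedList(f"q{i}", [i, 99], np.array([1.0, 0.0]))
                  for i in range(5)]
        for k in (1, 3):
            assert recall_at_k(ranked, list(range(5)), k) == 100.0

    def test_matches_membership_oracle(self, rng):
        ranked, truths = [], []
        for q in range(200):
            scores = rng.normal(size=8)
            ranked.append(rank_candidates(scores, query_id=f"q{q}"))
            truths.append(int(rng.integers(8)))
        for k in (1, 3, 5):
            oracle = 100.0 * np.mean([t in r.candidates[:k]
                                      for r, t in zip(ranked, truths)])
            assert recall_at_k(ranked, truths, k) == oracle

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_k(self, seed):
        r = np.random.default_rng(seed)
        ranked = [rank_candidates(r.normal(size=6)) for _ in range(20)]
        truths = [int(r.integers(6)) for _ in range(20)]
        values = [recall_at_k(ranked, truths, k) for k in range(1, 7)]
        assert values == sorted(values)
        assert values[-1] == 100.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            recall_at_k([], [], 0)


class TestRAtSum:
    def test_printed_row_arithmetic(self):
        assert r_at_sum([31.9, 54.2, 65.8, 82.3, 43.2, 59.8, 64.4, 65.9]) == \
            pytest.approx(467.5)
        assert r_at_sum([99.8, 100, 100, 100, 100, 100]) == pytest.approx(599.8)

    def test_zeros(self):
        assert r_at_sum([0, 0, 0]) == 0.0

    def test_bound(self, rng):
        values = rng.uniform(0, 100, size=8)
        assert r_at_sum(values) <= 100 * 8

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            r_at_sum([101.0])


class TestPatchLabel:
    def test_truth_within_top_k(self):
        assert patch_label(["B", "A", "C"], "A", 3) == "A"

    def test_fallback_to_rank_one(self):
        assert patch_label(["B", "C", "D"], "A", 3) == "B"

    def test_k_one_boundary(self):
        assert patch_label(["A", "B"], "A", 1) == "A"
        assert patch_label(["B", "A"], "A", 1) == "B"

    def test_empty_ranking_errors(self):
        with pytest.raises(ValueError):
            patch_label([], "A", 1)


class TestWSIMajorityVote:
    def test_clear_majority(self):
        assert wsi_majority_vote(["A", "A", "C"]) == "A"

    def test_tie_breaks_by_score_sum(self):
        assert wsi_majority_vote(["A", "B"], [0.9, 0.7]) == "A"
        assert wsi_majority_vote(["A", "B"], [0.2, 0.7]) == "B"

    def test_matches_counting_oracle_when_unique(self, rng):
        labels_pool = list("ABCD")
        for _ in range(500):
            labels = [labels_pool[i] for i in rng.integers(0, 4, size=7)]
            counts = {l: labels.count(l) for l in set(labels)}
            top = max(counts.values())
            modal = [l for l, c in counts.items() if c == top]
            if len(modal) == 1:
                assert wsi_majority_vote(labels) == modal[0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wsi_majority_vote([])


def aggregation_oracle(probs, v):
    """Brute-force top-V masked aggregation over patches."""
    C = probs.shape[1]
    agg = np.zeros(C)
    for row in probs:
        keep = sorted(range(C), key=lambda c: (-row[c], c))[:v]
        for c in keep:
            agg[c] += row[c]
    return agg


class TestRecallAtKAtV:
    def test_worked_aggregation_success(self):
        p = np.array([[.40, .35, .15, .10],
                      [.30, .50, .10, .10],
                      [.45, .15, .30, .10]])
        vote = recall_at_k_at_v(p, voting_threshold=2, k=1, true_index=0)
        assert np.allclose(vote.scores, [1.15, 0.85, 0.30, 0.0])
        assert vote.success

    def test_worked_aggregation_failure_then_success(self):
        p = np.array([[.30, .50, .10, .10],
                      [.30, .50, .10, .10],
                      [.40, .35, .15, .10]])
        at1 = recall_at_k_at_v(p, 2, 1, 0)
        assert np.allclose(at1.scores, [1.00, 1.35, 0.0, 0.0])
        assert not at1.success
        assert recall_at_k_at_v(p, 2, 2, 0).success

    def test_full_inclusion_always_succeeds(self, rng):
        for _ in range(20):
            p = rng.uniform(0.01, 1.0, size=(4, 5))
            assert recall_at_k_at_v(p, 5, 5, int(rng.integers(5))).success

    def test_single_patch_degenerates_to_top_k(self, rng):
        scores = rng.uniform(0.01, 1.0, size=6)
        truth = int(rng.integers(6))
        order = list(np.argsort(-scores, kind="stable"))
        for k in (1, 2, 3):
            vote = recall_at_k_at_v(scores[None, :], 6, k, truth)
            assert vote.success == (truth in order[:k])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n, C = int(rng.integers(1, 6)), int(rng.integers(2, 8))
            raw = rng.uniform(0.01, 1.0, size=(n, C))
            v = int(rng.integers(1, C + 1))
            vote = recall_at_k_at_v(raw, v, 1, 0)
            probs = raw / raw.sum(axis=1, keepdims=True)
            assert np.allclose(vote.scores, aggregation_oracle(probs, v),
                               atol=1e-12)

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(ValueError):
            recall_at_k_at_v(np.array([[0.5, -0.1]]), 1, 1, 0)

    def test_softmax_mode_accepts_negative_scores(self):
        vote = recall_at_k_at_v(np.array([[-1.0, 2.0]]), 1, 1, 1,
                                normalize="softmax")
        assert vote.success


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        cm = confusion_matrix_at_k(list("AABBC"), list("AABBC"), list("ABC"))
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))
        assert cm.accuracy == 1.0

    def test_row_sums_are_class_counts(self, rng):
        classes = list("ABCD")
        truths = [classes[i] for i in rng.integers(0, 4, size=50)]
        assigned = [classes[i] for i in rng.integers(0, 4, size=50)]
        cm = confusion_matrix_at_k(assigned, truths, classes)
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == truths.count(c)

    def test_matches_counting_oracle(self, rng):
        classes = list(range(5))
        truths = rng.integers(0, 5, size=200).tolist()
        assigned = rng.integers(0, 5, size=200).tolist()
        cm = confusion_matrix_at_k(assigned, truths, classes)
        oracle = np.zeros((5, 5), dtype=int)
        for a, t in zip(assigned, truths):
            oracle[t, a] += 1
        assert np.array_equal(cm.counts, oracle)

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix_at_k(["Z"], ["A"], ["A", "B"])

    def test_trace_equals_classification_recall(self, rng):
        # labels assigned by the patch rule at K make trace/total == R@K-as-
        # classification under that rule
        classes = list(range(4))
        rankings, truths = [], []
        for _ in range(100):
            order = list(rng.permutation(4))
            rankings.append(order)
            truths.append(int(rng.integers(4)))
        k = 2
        assigned = [patch_label(r, t, k) for r, t in zip(rankings, truths)]
        cm = confusion_matrix_at_k(assigned, truths, classes)
        frac_correct = np.mean([t in r[:k] for r, t in zip(rankings, truths)])
        assert cm.accuracy == pytest.approx(frac_correct)
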