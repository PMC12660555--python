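import numpy as np
import pytest

from ehrfusion.metrics import (
    classification_metrics,
    full_report,
    ndcg_at_k,
    recall_at_k,
)


class TestClassificationMetrics:
    def test_perfect_predictions(self, rng):
        T = (rng.random((6, 4)) < 0.5).astype(float)
        T[0, 0] = 1.0  # ensure at least one positive label
        rep = classification_metrics(T, T)
        assert rep.recall == 1.0 and rep.accuracy == 1.0
        assert rep.f1_weighted == 1.0

    def test_all_negative_decisions_give_zero_recall(self):
        T = np.array([[1.0, 0.0], [1.0, 1.0]])
        rep = classification_metrics(T, np.zeros_like(T))
        assert rep.recall == 0.0 and rep.precision == 0.0

    def test_hand_tallied_confusion_counts(self):
        # 3 samples x 2 labels; label 0: TP=1 FP=1 FN=1 TN=0 -> P=R=0.5 F1=0.5
        #                        label 1: TP=1 FP=0 FN=0 TN=2 -> P=R=F1=1
        T = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        D = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        rep = classification_metrics(T, D)
        np.testing.assert_allclose(rep.precision, 0.75)
        np.testing.assert_allclose(rep.recall, 0.75)
        np.testing.assert_allclose(rep.f1_macro, 0.75)
        # weighted by support (2, 1): (2*0.5 + 1*1.0)/3
        np.testing.assert_allclose(rep.f1_weighted, 2 / 3)
        np.testing.assert_allclose(rep.accuracy, 4 / 6)

    def test_subset_accuracy_mode(self):
        T = np.array([[1.0, 0.0], [1.0, 1.0]])
        D = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert classification_metrics(T, D, subset_accuracy=True).accuracy == 0.5

    def test_sample_permutation_invariance(self, rng):
        T = (rng.random((8, 5)) < 0.4).astype(float)
        D = (rng.random((8, 5)) < 0.4).astype(float)
        perm = rng.permutation(8)
        a = classification_metrics(T, D)
        b = classification_metrics(T[perm], D[perm])
        assert a == b

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros((0, 3)), np.zeros((0, 3)))


class TestRecallAtK:
    def test_full_list_recovers_everything(self, rng):
        T = (rng.random((5, 4)) < 0.5).astype(float)
        T[:, 0] = 1.0
        P = rng.random((5, 4))
        assert recall_at_k(T, P, 4) == 1.0

    def test_set_intersection_example(self):
        # positives {0, 2}; top-3 by probability = {0, 1, 3} -> recall 1/2
        T = np.array([[1.0, 0.0, 1.0, 0.0, 0.0]])
        P = np.array([[0.9, 0.8, 0.1, 0.7, 0.0]])
        assert recall_at_k(T, P, 3) == 0.5

    def test_label_free_patients_are_excluded(self):
        T = np.array([[0.0, 0.0], [1.0, 0.0]])
        P = np.array([[0.5, 0.5], [0.9, 0.1]])
        assert recall_at_k(T, P, 1) == 1.0

    def test_all_label_free_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            out = recall_at_k(np.zeros((2, 3)), np.random.rand(2, 3), 1)
        assert np.isnan(out)

    def test_k_above_d_clamped_with_warning(self):
        T = np.array([[1.0, 0.0]])
        P = np.array([[0.9, 0.1]])
        with pytest.warns(UserWarning, match="clamped"):
            assert recall_at_k(T, P, 5) == 1.0

    def test_monotone_in_k(self, rng):
        T = (rng.random((10, 6)) < 0.4).astype(float)
        T[0, 0] = 1.0
        P = rng.random((10, 6))
        values = [recall_at_k(T, P, k) for k in range(1, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0


class TestNDCG:
    def test_ideal_ranking_scores_one(self):
        T = np.array([[1.0, 1.0, 0.0, 0.0]])
        P = np.array([[0.9, 0.8, 0.2, 0.1]])
        np.testing.assert_allclose(ndcg_at_k(T, P, 4), 1.0)

    def test_single_relevant_at_rank_two(self):
        T = np.array([[0.0, 1.0, 0.0]])
        P = np.array([[0.9, 0.8, 0.1]])
        np.testing.assert_allclose(ndcg_at_k(T, P, 3), 1 / np.log2(3), atol=1e-9)

    def test_ties_break_by_label_index(self):
        T = np.array([[0.0, 1.0]])
        P = np.array([[0.5, 0.5]])  # tie -> label 0 ranked first
        np.testing.assert_allclose(ndcg_at_k(T, P, 2), 1 / np.log2(3), atol=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        T = (rng.random((20, 5)) < 0.4).astype(float)
        T[0, 0] = 1.0
        P = rng.random((20, 5))
        for k in range(1, 6):
            v = ndcg_at_k(T, P, k)
            assert 0.0 <= v <= 1.0


def brute_force_recall_at_k(T, P, k):
    vals = []
    for t, p in zip(T, P):
        pos = {i for i in range(len(t)) if t[i] == 1}
        if not pos:
            continue
        ranked = sorted(range(len(p)), key=lambda i: (-p[i], i))[:k]
        vals.append(len(pos & set(ranked)) / len(pos))
    return sum(vals) / len(vals)


def brute_force_ndcg_at_k(T, P, k):
    vals = []
    for t, p in zip(T, P):
        n_pos = int(sum(t))
        if n_pos == 0:
            continue
        ranked = sorted(range(len(p)), key=lambda i: (-p[i], i))[:k]
        dcg = sum((2 ** t[i] - 1) / np.log2(r + 2) for r, i in enumerate(ranked))
        idcg = sum(1 / np.log2(r + 2) for r in range(min(k, n_pos)))
        vals.append(dcg / idcg)
    return sum(vals) / len(vals)


def test_ranking_metrics_match_bruteforce_on_random_fixtures(rng):
    for _ in range(20):
        n, d = int(rng.integers(1, 20)), int(rng.integers(3, 8))
        T = (rng.random((n, d)) < 0.4).astype(float)
        if not T.any():
            T[0, 0] = 1.0
        P = rng.random((n, d))
        k = int(rng.integers(1, d + 1))
        np.testing.assert_allclose(
            recall_at_k(T, P, k), brute_force_recall_at_k(T, P, k), atol=1e-12
        )
        np.testing.assert_allclose(
            ndcg_at_k(T, P, k), brute_force_ndcg_at_k(T, P, k), atol=1e-12
        )


def test_full_report_includes_all_ks(rng):
    T = (rng.random((6, 5)) < 0.5).astype(float)
    T[0, 0] = 1.0
    P = rng.random((6, 5))
    D = (P >= 0.5).astype(float)
    rep = full_report(T, P, D, ks=(1, 2, 3))
    assert set(rep.recall_at_k) == {1, 2, 3}
    assert set(rep.ndcg_at_k) == {1, 2, 3}
    payload = rep.to_dict()
    assert set(payload["recall_at_k"]) == {"1", "2", "3"}
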