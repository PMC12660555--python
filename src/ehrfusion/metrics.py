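"""Multilabel classification and ranking metrics.

Classification metrics come from label-wise confusion counts (delegated to
scikit-learn): macro-averaged precision/recall, macro and support-weighted
F1, and per-cell accuracy (the fraction of correct label decisions over all
sample x label cells; subset accuracy is available by flag).

Ranking metrics score the predicted probability ordering per patient:
Recall@k is the fraction of a patient's true diagnoses among the k
highest-probability labels, and NDCG@k discounts relevant labels by their
rank, DCG@k = sum_{i<=k} (2^rel_i - 1)/log2(i+1), normalized by the ideal
DCG truncated at min(k, #positives).  Patients without any positive label
are excluded from both averages; ranking ties break deterministically by
ascending label index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

DEFAULT_KS = (1, 2, 3, 4, 5)


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1_macro: float
    f1_weighted: float
    accuracy: float
    recall_at_k: dict[int, float] = field(default_factory=dict)
    ndcg_at_k: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1_macro": self.f1_macro,
            "f1_weighted": self.f1_weighted,
            "accuracy": self.accuracy,
            "recall_at_k": {str(k): v for k, v in self.recall_at_k.items()},
            "ndcg_at_k": {str(k): v for k, v in self.ndcg_at_k.items()},
        }


def classification_metrics(targets, decisions, subset_accuracy: bool = False) -> MetricReport:
    """Label-wise confusion metrics over a batch of binary decision vectors."""
    T = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    D = np.atleast_2d(np.asarray(decisions, dtype=np.float64))
    if T.shape != D.shape:
        raise ValueError(f"shape mismatch: targets {T.shape} vs decisions {D.shape}")
    if T.shape[0] == 0:
        raise ValueError("empty batch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-support labels are defined as 0
        p_macro, r_macro, f_macro, _ = precision_recall_fscore_support(
            T, D, average="macro", zero_division=0
        )
        _, _, f_weighted, _ = precision_recall_fscore_support(
            T, D, average="weighted", zero_division=0
        )
    if subset_accuracy:
        acc = float(np.mean(np.all(T == D, axis=1)))
    else:
        acc = float(np.mean(T == D))
    return MetricReport(
        precision=float(p_macro),
        recall=float(r_macro),
        f1_macro=float(f_macro),
        f1_weighted=float(f_weighted),
        accuracy=acc,
    )


def _rankings(probabilities: np.ndarray) -> np.ndarray:
    """Label indices per patient, sorted by descending probability.

    Ties break by ascending label index (stable sort on the negated scores).
    """
    return np.argsort(-probabilities, axis=1, kind="stable")


def _check_ranking_inputs(targets, probabilities, k):
    T = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    P = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: targets {T.shape} vs probabilities {P.shape}")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = T.shape[1]
    if k > d:
        warnings.warn(f"k={k} exceeds the number of labels d={d}; clamped to {d}")
        k = d
    return T, P, k


def recall_at_k(targets, probabilities, k: int) -> float:
    """Mean fraction of true diagnoses captured by the top-k predictions."""
    T, P, k = _check_ranking_inputs(targets, probabilities, k)
    order = _rankings(P)
    values = []
    for t, o in zip(T, order):
        positives = np.flatnonzero(t)
        if positives.size == 0:
            continue
        hits = np.intersect1d(positives, o[:k]).size
        values.append(hits / positives.size)
    if not values:
        warnings.warn("no patient with a positive label; Recall@k undefined")
        return float("nan")
    return float(np.mean(values))


def ndcg_at_k(targets, probabilities, k: int) -> float:
    """Mean normalized discounted cumulative gain of the predicted ranking."""
    T, P, k = _check_ranking_inputs(targets, probabilities, k)
    order = _rankings(P)
    discounts = 1.0 / np.log2(np.arange(1, k + 1) + 1.0)
    values = []
    for t, o in zip(T, order):
        n_pos = int(t.sum())
        if n_pos == 0:
            continue
        rel = t[o[:k]]  # binary relevance: 2^rel - 1 is rel itself
        dcg = float((rel * discounts).sum())
        idcg = float(discounts[: min(k, n_pos)].sum())
        values.append(dcg / idcg)
    if not values:
        warnings.warn("no patient with a positive label; NDCG@k undefined")
        return float("nan")
    return float(np.mean(values))


def full_report(
    targets, probabilities, decisions, ks: tuple[int, ...] = DEFAULT_KS,
    subset_accuracy: bool = False,
) -> MetricReport:
    """Classification metrics plus Recall@k / NDCG@k for every k in ``ks``."""
    report = classification_metrics(targets, decisions, subset_accuracy=subset_accuracy)
    report.recall_at_k = {k: recall_at_k(targets, probabilities, k) for k in ks}
    report.ndcg_at_k = {k: ndcg_at_k(targets, probabilities, k) for k in ks}
    return report
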