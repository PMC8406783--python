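"""Evaluation metrics for sample-label prediction and gene prioritization.

The label metrics are multi-label ranking criteria specialized to
single-label truth: Hamming loss counts mismatched indicator cells,
one-error counts samples whose top-scoring category is wrong, and coverage
measures how far down the category ranking the true label sits.  Gene
prioritization against a binary gold standard is scored by ROC AUC
(Mann-Whitney, ties count one half) and by the area under the
precision-recall step curve.  Fold-change and Welch t-statistic scorers are
provided as the classical two-group baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class ScoreTable:
    """Items with confidence scores (higher = more positive) and binary truth."""

    item_ids: tuple[str, ...]
    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        truth = np.asarray(self.truth, dtype=int)
        if scores.shape != truth.shape or scores.ndim != 1:
            raise ValidationError("scores and truth must be 1-D and equal length")
        if len(self.item_ids) != scores.shape[0]:
            raise ValidationError("item_ids length does not match scores")
        if not np.all(np.isin(truth, (0, 1))):
            raise ValidationError("truth must be binary 0/1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "truth", truth)


def _as_labels(x, c: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=int)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D")
    if np.any((arr < 1) | (arr > c)):
        raise ValidationError(f"{name} entries must lie in 1..{c}")
    return arr


def hamming_loss(pred_labels, true_labels, c: int) -> float:
    """Mean indicator-cell mismatch over samples and categories.

    For single-label truth each misclassified sample flips two indicator
    cells, so this equals ``2/c`` times the misclassification rate.
    """
    pred = _as_labels(pred_labels, c, "pred_labels")
    true = _as_labels(true_labels, c, "true_labels")
    if pred.shape != true.shape:
        raise ValidationError("label vectors differ in length")
    return float(2.0 * np.mean(pred != true) / c)


def one_error(score_matrix, true_labels) -> float:
    """Fraction of samples whose top-scoring category is not the true one.

    Argmax ties resolve to the smallest category index.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2:
        raise ValidationError("score_matrix must be 2-D")
    true = _as_labels(true_labels, S.shape[1], "true_labels")
    if true.shape[0] != S.shape[0]:
        raise ValidationError("score matrix and labels differ in length")
    top = np.argmax(S, axis=1) + 1
    return float(np.mean(top != true))


def coverage(score_matrix, true_labels) -> float:
    """Mean zero-based rank of the true category in the descending score order.

    0 means the true label always ranks first; ties resolve toward the
    smaller category index (stable descending order).
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2:
        raise ValidationError("score_matrix must be 2-D")
    true = _as_labels(true_labels, S.shape[1], "true_labels")
    if true.shape[0] != S.shape[0]:
        raise ValidationError("score matrix and labels differ in length")
    ranks = np.empty(S.shape[0], dtype=float)
    for i in range(S.shape[0]):
        order = np.argsort(-S[i], kind="stable")
        ranks[i] = int(np.flatnonzero(order == true[i] - 1)[0])
    return float(np.mean(ranks))


def _scores_truth(table_or_scores, truth=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table_or_scores, ScoreTable):
        return table_or_scores.scores, table_or_scores.truth
    scores = np.asarray(table_or_scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth differ in length")
    return scores, truth


def roc_auc(table_or_scores, truth=None) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    scores, t = _scores_truth(table_or_scores, truth)
    if len(np.unique(t)) < 2:
        raise ValidationError("ROC AUC needs at least one positive and one negative")
    return float(roc_auc_score(t, scores))


def aupr(table_or_scores, truth=None) -> float:
    """Area under the precision-recall step curve (no interpolation)."""
    scores, t = _scores_truth(table_or_scores, truth)
    if not np.any(t == 1):
        raise ValidationError("AUPR needs at least one positive")
    return float(average_precision_score(t, scores))


def _group_values(xm: ExpressionMatrix, sample_ids) -> np.ndarray:
    index = {s: i for i, s in enumerate(xm.sample_ids)}
    missing = [s for s in sample_ids if s not in index]
    if missing:
        raise ValidationError(f"unknown sample ids: {missing}")
    return xm.values[[index[s] for s in sample_ids], :]


def fold_change_scores(
    xm: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-gene ``|log2((mean_a + pc) / (mean_b + pc))|``; higher = more differential."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    a = _group_values(xm, group_a).mean(axis=0)
    b = _group_values(xm, group_b).mean(axis=0)
    return np.abs(np.log2((a + pseudocount) / (b + pseudocount)))


def t_test_scores(xm: ExpressionMatrix, group_a, group_b) -> np.ndarray:
    """Per-gene |Welch t statistic| between two sample groups.

    Genes with zero variance and equal means in both groups score 0.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    a = _group_values(xm, group_a)
    b = _group_values(xm, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(a, b, axis=0, equal_var=False).statistic
    return np.abs(np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf))
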