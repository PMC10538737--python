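"""Held-out classification performance: confusion matrix, accuracy, AUCs.

Predicted status uses the strict rule yhat = 1 iff pihat > cutoff (default
0.5).  ROC-AUC is the Mann-Whitney probability with midrank tie handling;
PR-AUC is the step-wise average-precision form, preferred here because PE
cohorts are imbalanced (~19% positive).  ``evaluate_split`` refits a
learner on the training rows restricted to a feature subset, which is how
the all-features vs selected-features comparison is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import CohortTable, SplitSpec
from .learners import fit_learner

__all__ = ["EvalReport", "confusion_matrix", "roc_auc", "pr_auc", "evaluate_split"]


@dataclass(frozen=True)
class EvalReport:
    """Test-set classification report at a probability cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    roc_auc: float
    pr_auc: float
    cutoff: float
    n_test: int

    def __post_init__(self):
        assert self.tp + self.fp + self.fn + self.tn == self.n_test

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_matrix(
    prob: np.ndarray, Y: np.ndarray, cutoff: float = 0.5
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) with yhat = 1 iff prob > cutoff (strictly)."""
    prob, Y = np.asarray(prob), np.asarray(Y)
    if prob.shape != Y.shape:
        raise ValueError(f"length mismatch: {prob.shape} vs {Y.shape}")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    yhat = prob > cutoff
    tp = int(np.sum(yhat & (Y == 1)))
    fp = int(np.sum(yhat & (Y == 0)))
    fn = int(np.sum(~yhat & (Y == 1)))
    tn = int(np.sum(~yhat & (Y == 0)))
    return tp, fp, fn, tn


def roc_auc(prob: np.ndarray, Y: np.ndarray) -> float:
    """P(score_case > score_control) + 0.5 P(equal), via midranks."""
    Y = np.asarray(Y)
    if len(np.unique(Y)) < 2:
        raise ValueError("ROC-AUC undefined with a single outcome class")
    return float(roc_auc_score(Y, prob))


def pr_auc(prob: np.ndarray, Y: np.ndarray) -> float:
    """Step-wise average precision (no linear interpolation)."""
    Y = np.asarray(Y)
    if Y.sum() == 0:
        raise ValueError("PR-AUC undefined without positive cases")
    return float(average_precision_score(Y, prob))


def evaluate_split(
    cohort: CohortTable,
    split: SplitSpec,
    learner_kind: str,
    feature_subset: list[str] | None = None,
    configs: dict | None = None,
    seed: int = 0,
    cutoff: float = 0.5,
) -> EvalReport:
    """Fit on the training rows (optionally restricted to a feature subset),
    score the test rows, and return an :class:`EvalReport`."""
    sub = cohort if not feature_subset else cohort.subset_features(feature_subset)
    train = sub.subset_rows(split.train_idx)
    test = sub.subset_rows(split.test_idx)
    est = fit_learner(train, learner_kind, configs, seed=seed)
    prob = est.predict_prob(test.X)
    tp, fp, fn, tn = confusion_matrix(prob, test.Y, cutoff)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / test.n,
        roc_auc=roc_auc(prob, test.Y),
        pr_auc=pr_auc(prob, test.Y),
        cutoff=cutoff, n_test=test.n,
    )
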