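"""Per-fold and ensemble evaluation.

The five fold-trained classifiers vote on each test segment; the ensemble
label is the majority, and the continuous ensemble score used for the ROC
curve is the mean of the per-model sepsis probabilities (a majority vote is
binary, so a separate continuous score is needed for a ROC).  Metrics are
sample-level: accuracy, sensitivity (sepsis recall) and specificity
(control recall), plus the ROC/AUC of the ensemble score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix, roc_curve

__all__ = [
    "ConfusionCounts",
    "EnsembleResult",
    "MajorityVoteEnsemble",
    "majority_vote",
    "ensemble_score",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_ensemble",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for an empty class."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with sepsis as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EnsembleResult:
    per_model_predictions: np.ndarray  # (k, N) binary
    per_model_scores: np.ndarray  # (k, N) probabilities
    vote: np.ndarray  # (N,) binary
    score: np.ndarray  # (N,) mean probability
    per_model_metrics: List[Dict[str, float]]
    ensemble_metrics: Dict[str, float]
    roc: np.ndarray  # (n_points, 2) = (FPR, TPR)
    auc: float

    def report(self) -> pd.DataFrame:
        """Per-fold rows plus an ensemble row (accuracy/sensitivity/specificity, %)."""
        rows = []
        for i, m in enumerate(self.per_model_metrics):
            rows.append({"model": f"Fold {i}", **{k: 100 * v for k, v in m.items()}})
        rows.append({"model": "Ensemble",
                     **{k: 100 * v for k, v in self.ensemble_metrics.items()}})
        return pd.DataFrame(rows)


def majority_vote(votes: Sequence[int]) -> int:
    """Label receiving more than half of an odd number of binary votes."""
    votes = np.asarray(votes)
    k = votes.size
    if k % 2 == 0:
        raise ValueError("majority vote requires an odd number of voters")
    return int(votes.sum() > k / 2)


def ensemble_score(probs: Sequence[float]) -> float:
    """Arithmetic mean of the per-model sepsis probabilities."""
    p = np.asarray(probs, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.mean())


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with the positive class encoded as 1 (sepsis)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionCounts(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp))


def metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, sensitivity and specificity as fractions in [0, 1]."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise UndefinedMetricError("both classes must be represented")
    return {
        "accuracy": (counts.tp + counts.tn) / counts.n,
        "sensitivity": counts.tp / (counts.tp + counts.fn),
        "specificity": counts.tn / (counts.tn + counts.fp),
    }


def roc_auc(scores: Sequence[float], y_true: Sequence[int]) -> Tuple[np.ndarray, float]:
    """ROC points by threshold sweep and trapezoid AUC.

    Ties in the scores cross the corresponding thresholds simultaneously.
    Requires both classes present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC undefined with a single class")
    fpr, tpr, _ = roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr]), float(sk_auc(fpr, tpr))


class MajorityVoteEnsemble(BaseEstimator, ClassifierMixin):
    """Majority-vote ensemble over an odd number of fitted binary classifiers.

    ``predict`` takes the label predicted by more than half of the member
    models (each thresholding its positive-class probability at 0.5);
    ``predict_proba`` averages the member probabilities, which provides the
    continuous score used for ROC analysis.
    """

    def __init__(self, estimators=()):
        self.estimators = list(estimators)

    def fit(self, X=None, y=None):
        if len(self.estimators) % 2 == 0 or not self.estimators:
            raise ValueError("an odd number of member classifiers is required")
        self.estimators_ = list(self.estimators)
        self.classes_ = np.asarray(getattr(self.estimators_[0], "classes_", [0, 1]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        probs = np.stack([m.predict_proba(X) for m in self.estimators_])
        return probs.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        votes = np.stack([(m.predict_proba(X)[:, 1] >= 0.5).astype(int)
                          for m in self.estimators_])
        vote = np.array([majority_vote(votes[:, j]) for j in range(votes.shape[1])])
        return self.classes_[vote]


def evaluate_ensemble(
    trained_folds: Sequence,
    X_test: np.ndarray,
    y_test: Sequence[int],
    test_subjects: Optional[Sequence] = None,
    train_subjects: Optional[Set[str]] = None,
) -> EnsembleResult:
    """Evaluate fold-trained classifiers and their majority-vote ensemble.

    ``trained_folds`` may hold fitted classifiers or ``TrainedFold`` objects.
    ``y_test`` uses 1 for sepsis.  When subject identifiers are provided for
    both sides, overlap between test and training subjects raises.
    """
    if test_subjects is not None and train_subjects is not None:
        overlap = set(map(str, test_subjects)) & set(map(str, train_subjects))
        if overlap:
            raise ValueError(f"test subjects seen in training: {sorted(overlap)[:5]}")
    models = [getattr(tf, "weights_ref", tf) for tf in trained_folds]
    y_test = np.asarray(y_test)
    k = len(models)
    n = X_test.shape[0]
    scores = np.empty((k, n))
    preds = np.empty((k, n), dtype=int)
    per_model = []
    for i, m in enumerate(models):
        scores[i] = m.predict_proba(X_test)[:, 1]
        preds[i] = (scores[i] >= 0.5).astype(int)
        per_model.append(metrics(confusion(y_test, preds[i])))
    vote = np.array([majority_vote(preds[:, j]) for j in range(n)])
    mean_score = scores.mean(axis=0)
    ens_metrics = metrics(confusion(y_test, vote))
    roc, auc_val = roc_auc(mean_score, y_test)
    return EnsembleResult(
        per_model_predictions=preds,
        per_model_scores=scores,
        vote=vote,
        score=mean_score,
        per_model_metrics=per_model,
        ensemble_metrics=ens_metrics,
        roc=roc,
        auc=auc_val,
    )


def subject_level_report(result: EnsembleResult, y_test: Sequence[int],
                         subjects: Sequence[str]) -> pd.DataFrame:
    """Secondary aggregation: majority of each subject's segment votes."""
    df = pd.DataFrame({"subject": list(map(str, subjects)),
                       "y": np.asarray(y_test), "vote": result.vote})
    agg = df.groupby("subject").agg(y=("y", "first"),
                                    frac_sepsis=("vote", "mean"))
    agg["pred"] = (agg["frac_sepsis"] > 0.5).astype(int)
    return agg.reset_index()
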