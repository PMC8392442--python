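"""Leave-one-out cross-validation harness and confusion-matrix metrics.

Every fold holds out exactly one pattern, recomputes the relevance
permutation and retrains the minimalist classifier on the remaining
``m - 1`` patterns (no information from the held-out pattern leaks into
its fold's model), then classifies the held-out pattern.  The per-fold
verdicts are aggregated into a single 2x2 confusion matrix from which
accuracy, sensitivity and specificity derive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Undefined ratios (an empty positive or negative class) are reported as
NaN with a warning rather than silently as 0.  The whole procedure is
deterministic and therefore exactly repeatable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dmeans import FeatureDataset
from .mml import assign_class, train

__all__ = [
    "ConfusionMatrix",
    "FoldRecord",
    "EvaluationResult",
    "confusion",
    "metrics",
    "imbalance_ratio",
    "loocv",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_label: object

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "positive_label": str(self.positive_label),
        }


def confusion(y_true: Sequence, y_pred: Sequence, positive_label) -> ConfusionMatrix:
    """Tally the standard 2x2 confusion matrix.

    Labels not belonging to the two observed classes raise an error.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("true and predicted label sequences must have equal length")
    labels = set(y_true.tolist()) | set(y_pred.tolist())
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} absent from the labels")
    if len(labels) > 2:
        raise ValueError(f"more than two distinct labels encountered: {sorted(map(str, labels))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        positive_label=positive_label,
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of a confusion matrix.

    An undefined sensitivity (no positives) or specificity (no negatives)
    is returned as NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics of an all-zero confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn == 0:
        warnings.warn("sensitivity undefined: no positive patterns evaluated")
        sensitivity = float("nan")
    else:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    if cm.tn + cm.fp == 0:
        warnings.warn("specificity undefined: no negative patterns evaluated")
        specificity = float("nan")
    else:
        specificity = cm.tn / (cm.tn + cm.fp)
    return accuracy, sensitivity, specificity


def imbalance_ratio(ds: FeatureDataset) -> float:
    """Majority-class count over minority-class count (>= 1)."""
    c1, c2 = ds.classes
    n1 = int(ds.class_mask(c1).sum())
    n2 = int(ds.class_mask(c2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty")
    return max(n1, n2) / min(n1, n2)


@dataclass(frozen=True)
class FoldRecord:
    index: int
    true_label: object
    predicted_label: object
    k_star: int
    hypothesis: float


@dataclass(frozen=True)
class EvaluationResult:
    """Aggregated LOOCV outcome: per-fold records plus global metrics."""

    folds: tuple
    confusion_matrix: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    config: dict = field(default_factory=dict)

    @property
    def k_star_counts(self) -> dict:
        """How often each selected prefix length occurred across folds."""
        counts: dict[int, int] = {}
        for f in self.folds:
            counts[f.k_star] = counts.get(f.k_star, 0) + 1
        return dict(sorted(counts.items()))

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": [f.index for f in self.folds],
                "true_label": [f.true_label for f in self.folds],
                "predicted_label": [f.predicted_label for f in self.folds],
                "k_star": [f.k_star for f in self.folds],
                "hypothesis": [f.hypothesis for f in self.folds],
            }
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion_matrix.to_dict(),
            "k_star_counts": {str(k): v for k, v in self.k_star_counts.items()},
            "config": self.config,
            "folds": [
                {
                    "fold": f.index,
                    "true_label": str(f.true_label),
                    "predicted_label": str(f.predicted_label),
                    "k_star": f.k_star,
                    "hypothesis": f.hypothesis,
                }
                for f in self.folds
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def loocv(
    ds: FeatureDataset,
    *,
    positive_label=None,
    mode: str = "signed",
    k_schedule: Sequence[int] | None = None,
    tie_policy: str = "below",
) -> EvaluationResult:
    """Leave-one-out cross-validation of the minimalist classifier.

    For each of the ``m`` folds the relevance permutation and the model
    are recomputed on the remaining ``m - 1`` patterns only, then the
    held-out pattern is classified.  Each class must contribute at least
    2 patterns so that no fold empties a class.

    ``positive_label`` defaults to the smaller of the two class labels
    (the disease class "IVH" sorts before "Normal" in the image workflow).
    """
    if ds.m < 3:
        raise ValueError("LOOCV needs at least 3 patterns")
    c1, c2 = ds.classes
    if ds.class_mask(c1).sum() < 2 or ds.class_mask(c2).sum() < 2:
        raise ValueError("each class needs >= 2 patterns so every fold keeps both classes")
    if positive_label is None:
        positive_label = c1
    elif positive_label not in ds.classes:
        raise ValueError(f"positive label {positive_label!r} not among the classes")

    folds = []
    y_true, y_pred = [], []
    keep = np.ones(ds.m, dtype=bool)
    for i in range(ds.m):
        keep[i] = False
        tr = ds.subset(keep)
        keep[i] = True
        model, _ = train(tr, mode=mode, k_schedule=k_schedule, tie_policy=tie_policy)
        pred = assign_class(model, ds.patterns[i])
        folds.append(
            FoldRecord(
                index=i,
                true_label=ds.labels[i],
                predicted_label=pred,
                k_star=model.k_star,
                hypothesis=model.hypothesis,
            )
        )
        y_true.append(ds.labels[i])
        y_pred.append(pred)

    cm = confusion(y_true, y_pred, positive_label)
    acc, sens, spec = metrics(cm)  # both classes non-empty: always defined
    return EvaluationResult(
        folds=tuple(folds),
        confusion_matrix=cm,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        config={
            "mode": mode,
            "k_schedule": None if k_schedule is None else list(map(int, k_schedule)),
            "tie_policy": tie_policy,
            "positive_label": str(positive_label),
        },
    )
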