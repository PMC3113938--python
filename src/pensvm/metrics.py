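"""Performance measures for discrete binary classifiers.

A fitted SVM predicts a hard -1/+1 label, so its ROC "curve" is the single
point (1 - specificity, sensitivity) joined to the corners, and the area under
that curve reduces to (sensitivity + specificity)/2 = (Youden index + 1)/2.
The Youden index (sensitivity + specificity - 1) weights both error types
equally: 1 for a perfect classifier, 0 in expectation for a random one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "misclassification_rate",
    "youden",
    "auc_discrete",
    "summary_row",
    "write_metrics_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with +1 as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.all(np.isin(arr, (-1.0, 1.0))):
            raise ValueError(f"{name} must contain only -1/+1 labels")
    pos = y_true == 1
    return ConfusionCounts(
        TP=int(np.sum(pos & (y_pred == 1))),
        FP=int(np.sum(~pos & (y_pred == 1))),
        TN=int(np.sum(~pos & (y_pred == -1))),
        FN=int(np.sum(pos & (y_pred == -1))),
    )


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when the evaluation set has no positives.

    An undefined rate is reported as missing rather than silently 0 so that
    aggregation can skip it.
    """
    denom = counts.TP + counts.FN
    return counts.TP / denom if denom else None


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when the evaluation set has no negatives."""
    denom = counts.TN + counts.FP
    return counts.TN / denom if denom else None


def misclassification_rate(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise ValueError("empty confusion table")
    return (counts.FP + counts.FN) / counts.total


def _check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def youden(sens: float, spec: float) -> float:
    """Youden index = sensitivity + specificity - 1, in [-1, 1]."""
    _check_proportion(sens, "sensitivity")
    _check_proportion(spec, "specificity")
    return sens + spec - 1.0


def auc_discrete(sens: float, spec: float) -> float:
    """AUC of a discrete classifier: (sensitivity + specificity)/2.

    Identical to (youden + 1)/2 — for a hard classifier AUC and Youden index
    carry the same information.
    """
    _check_proportion(sens, "sensitivity")
    _check_proportion(spec, "specificity")
    return (sens + spec) / 2.0


def summary_row(method: str, n_features: int, counts: ConfusionCounts) -> dict:
    """One row of a classifier summary table (percent-formatted rates)."""
    sens = sensitivity(counts)
    spec = specificity(counts)
    row = {
        "method": method,
        "n_features": n_features,
        "test_error_pct": round(100.0 * misclassification_rate(counts), 1),
        "sensitivity_pct": None if sens is None else round(100.0 * sens, 1),
        "specificity_pct": None if spec is None else round(100.0 * spec, 1),
    }
    if sens is None or spec is None:
        row["youden"] = None
        row["auc"] = None
    else:
        row["youden"] = round(youden(sens, spec), 3)
        row["auc"] = round(auc_discrete(sens, spec), 3)
    return row


def write_metrics_table(rows: list[dict], path, delimiter: str = "\t") -> None:
    """Write summary rows as a delimited table (# features, error %, ...)."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
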