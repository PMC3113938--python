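"""Shared data model: datasets, linear classifiers, penalty specs, fit results.

The package works with binary classification problems whose labels are coded
strictly as -1/+1; a linear classifier is the pair (w, b) defining the decision
function f(x) = w.x + b with predicted label sign(f(x)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Coefficients with absolute value below this threshold are treated as
#: redundant and removed from the active set of a fitted model.
REMOVAL_THRESHOLD = 1e-4

PENALTY_FAMILIES = ("ridge", "lasso", "scad", "elastic_net", "elastic_scad")


class ShapeError(ValueError):
    """Dimension mismatch between a model and the data it is applied to."""


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family plus its tuning parameters.

    Parameters
    ----------
    family:
        One of ``ridge``, ``lasso``, ``scad``, ``elastic_net``, ``elastic_scad``.
    lambda1:
        Weight of the sparsity-inducing part (L1 or SCAD). Ignored by ``ridge``.
    lambda2:
        Weight of the quadratic (ridge) part. Ignored by ``lasso``/``scad``/``ridge``.
    a:
        SCAD shape parameter, must exceed 2; 3.7 is the standard default.
    C:
        Soft-margin cost of the plain L2 SVM (only used by ``ridge``).
    """

    family: str
    lambda1: float = 0.0
    lambda2: float = 0.0
    a: float = 3.7
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in PENALTY_FAMILIES:
            raise ValueError(
                f"unknown penalty family {self.family!r}; expected one of {PENALTY_FAMILIES}"
            )
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if self.family in ("scad", "elastic_scad") and self.a <= 2:
            raise ValueError("SCAD shape parameter a must be > 2")
        if self.C < 0:
            raise ValueError("cost C must be nonnegative")


@dataclass
class Dataset:
    """Feature matrix with -1/+1 labels and identifiers.

    ``X`` has one row per sample and one column per feature; ``y`` holds the
    class labels, which must be exactly -1 or +1.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ShapeError(f"X must be 2-d, got shape {self.X.shape}")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ShapeError(f"y has shape {self.y.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be coded -1/+1")
        if not self.feature_ids:
            self.feature_ids = [f"f{j}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.feature_ids) != p:
            raise ShapeError("feature_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ShapeError("sample_ids length does not match number of rows")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature identifiers")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if not (np.any(self.y == 1) and np.any(self.y == -1)):
            raise ValueError("both classes (-1 and +1) must be present for fitting")

    def subset(self, idx: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            self.X[idx],
            self.y[idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class LinearModel:
    """Linear decision rule f(x) = w.x + b with its active-feature set.

    Every coefficient outside ``active_set`` is exactly zero. The tie-break
    sign(0) -> +1 makes predictions deterministic.
    """

    w: np.ndarray
    b: float
    penalty: PenaltySpec | None = None
    active_set: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = float(self.b)
        if self.active_set is None:
            self.active_set = np.flatnonzero(self.w != 0.0)
        else:
            self.active_set = np.asarray(self.active_set, dtype=int)

    @property
    def n_features(self) -> int:
        return self.w.shape[0]


@dataclass
class FitResult:
    """A fitted model together with its optimization trace."""

    model: LinearModel
    objective_trace: list[float] = field(default_factory=list)
    tuning_record: list | None = None

    @property
    def n_features_selected(self) -> int:
        return int(len(self.model.active_set))

    @property
    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else float("nan")


def _check_X(model: LinearModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1]} columns but the model has {model.w.shape[0]} coefficients"
        )
    return X


def decision_values(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Return f(x) = X w + b for every row of ``X``."""
    X = _check_X(model, X)
    return X @ model.w + model.b


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Predicted -1/+1 labels: sign of the decision value, with sign(0) := +1."""
    f = decision_values(model, X)
    return np.where(f >= 0.0, 1.0, -1.0)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature centering and unit-variance scaling.

    Penalties are not scale invariant, so scaling is opt-in and must be applied
    consistently to training and test data. Constant features get scale 1.
    Returns (X_scaled, mean, scale).
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return (X - mean) / scale, mean, scale
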