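"""Stratified cross-validation, fixed-grid search and EPSGO interval search.

Tuning a penalized SVM means minimizing the cross-validated misclassification
rate over one (lambda1, or C) or two (lambda1, lambda2) parameters. Besides an
exhaustive grid, the module implements an interval search in the style of
EPSGO/EGO: a Gaussian-process surrogate is fitted to the tuning points visited
so far and new candidates are proposed where the expected improvement of the
surrogate is largest, until the optimum has not changed for ten proposals.
All parameters are searched on the log2 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.model_selection import StratifiedKFold

from .core import Dataset, FitResult, PenaltySpec, predict
from .metrics import confusion, misclassification_rate, sensitivity, specificity

__all__ = [
    "CVPlan",
    "stratified_kfold",
    "CVResult",
    "cv_error",
    "grid_search",
    "SurrogateModel",
    "expected_improvement",
    "EPSGOResult",
    "epsgo_search",
    "TuningResult",
    "tune_parameters",
]


# ---------------------------------------------------------------------------
# stratified k-fold


@dataclass
class CVPlan:
    """A fixed assignment of samples to folds."""

    k: int
    fold_assignment: np.ndarray  # per-sample fold index in {0..k-1}
    seed: int
    stratified: bool = True

    def folds(self):
        for j in range(self.k):
            test = np.flatnonzero(self.fold_assignment == j)
            train = np.flatnonzero(self.fold_assignment != j)
            yield train, test


class StratificationError(ValueError):
    """A class has fewer members than the requested number of folds."""


def stratified_kfold(y: np.ndarray, k: int, seed: int) -> CVPlan:
    """Deterministic stratified k-fold plan.

    Folds partition the samples, and within each class the fold sizes differ
    by at most one, so each fold carries approximately the class distribution
    of the full data set.
    """
    y = np.asarray(y)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be between 2 and n={n}")
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise StratificationError(
                f"class {cls} has only {np.sum(y == cls)} members, fewer than k={k} folds"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for j, (_, test) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assignment[test] = j
    return CVPlan(k=k, fold_assignment=assignment, seed=seed, stratified=True)


# ---------------------------------------------------------------------------
# cross-validated error


@dataclass
class CVResult:
    mean_error: float
    fold_errors: list[float]
    fold_sensitivity: list[float | None]
    fold_specificity: list[float | None]
    n_failed: int = 0


def cv_error(data: Dataset, solver, plan: CVPlan) -> CVResult:
    """Mean held-out misclassification rate of ``solver`` under ``plan``.

    ``solver`` maps a training Dataset to a FitResult. A failing fold is
    skipped as long as at least k-1 folds succeed; otherwise the error is
    re-raised.
    """
    errors, sens, spec = [], [], []
    n_failed = 0
    last_exc = None
    for train, test in plan.folds():
        try:
            res: FitResult = solver(data.subset(train))
        except Exception as exc:  # noqa: BLE001 - recorded, bounded by k-1 rule
            n_failed += 1
            last_exc = exc
            continue
        y_pred = predict(res.model, data.X[test])
        counts = confusion(data.y[test], y_pred)
        errors.append(misclassification_rate(counts))
        sens.append(sensitivity(counts))
        spec.append(specificity(counts))
    if n_failed > 1 or not errors:
        raise RuntimeError(f"{n_failed}/{plan.k} folds failed") from last_exc
    return CVResult(
        mean_error=float(np.mean(errors)),
        fold_errors=errors,
        fold_sensitivity=sens,
        fold_specificity=spec,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# fixed grid search


def _prefer(point_a, value_a, point_b, value_b) -> bool:
    """True if (point_a, value_a) should replace (point_b, value_b) as best.

    Ties in the objective are broken toward the lexicographically larger
    parameter point: on the log2 scale of (lambda1, lambda2) this prefers the
    sparser, then smoother model.
    """
    if value_a < value_b:
        return True
    return value_a == value_b and tuple(np.atleast_1d(point_a)) > tuple(np.atleast_1d(point_b))


def grid_search(data: Dataset, solver_factory, grid, plan: CVPlan):
    """Evaluate every grid point and return (best_params, evaluations).

    ``solver_factory(params)`` must return a solver callable; ``grid`` is a
    sequence of parameter tuples (or scalars). Every point is evaluated — no
    skipping — and the argmin of the mean CV error is returned with the
    larger-parameter tie-break.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    evaluations = []
    best_params, best_value = None, math.inf
    for params in grid:
        cv = cv_error(data, solver_factory(params), plan)
        evaluations.append((params, cv.mean_error, cv.fold_errors))
        if best_params is None or _prefer(params, cv.mean_error, best_params, best_value):
            best_params, best_value = params, cv.mean_error
    return best_params, evaluations


# ---------------------------------------------------------------------------
# Gaussian-process surrogate + expected improvement


class SurrogateModel:
    """Noise-free GP interpolator of the tuning objective.

    Inputs are rescaled to the unit box and outputs standardized internally;
    a squared-exponential kernel with likelihood-fitted length scale and a
    1e-6 jitter is used. ``predict`` returns (mean, sd) on the original scale.
    """

    def __init__(self, bounds: np.ndarray, seed: int = 0):
        self.bounds = np.asarray(bounds, dtype=float)
        self.seed = seed
        self._gp = None
        self._y_mean = 0.0
        self._y_scale = 1.0
        self.X_ = None
        self.y_ = None

    def _scale(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.atleast_2d(X) - lo) / span

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurrogateModel":
        self.X_ = np.atleast_2d(np.asarray(X, dtype=float))
        self.y_ = np.asarray(y, dtype=float)
        self._y_mean = float(self.y_.mean())
        self._y_scale = float(self.y_.std()) or 1.0
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=np.full(self.X_.shape[1], 0.3),
            length_scale_bounds=(1e-2, 1e2),
        )
        self._gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=False,
            n_restarts_optimizer=2,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            # hyperparameters pushed to their bounds still yield a usable
            # interpolator; the acquisition only needs a rough surrogate
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gp.fit(self._scale(self.X_), (self.y_ - self._y_mean) / self._y_scale)
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, sd = self._gp.predict(self._scale(X), return_std=True)
        return mu * self._y_scale + self._y_mean, sd * self._y_scale


def expected_improvement(surrogate, candidate, best_observed: float):
    """EI for minimization: E[max(best - Y, 0)] under the surrogate's normal.

    ``surrogate`` may be a SurrogateModel (evaluated at ``candidate``) or a
    (mu, sigma) pair. EI is zero wherever the predictive sd is zero.
    """
    if isinstance(surrogate, tuple):
        mu, sd = (np.asarray(v, dtype=float) for v in surrogate)
    else:
        mu, sd = surrogate.predict(np.atleast_2d(candidate))
    mu, sd = np.atleast_1d(mu), np.atleast_1d(sd)
    improve = best_observed - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0, improve * norm.cdf(u) + sd * norm.pdf(u), 0.0)
    ei = np.maximum(ei, 0.0)
    return ei.item() if ei.size == 1 else ei


# ---------------------------------------------------------------------------
# EPSGO interval search


@dataclass
class EPSGOResult:
    best_point: np.ndarray
    best_value: float
    points: np.ndarray
    values: np.ndarray
    n_evals: int
    stopped_by: str
    ei_trace: list[float] = field(default_factory=list)


def epsgo_search(
    objective,
    bounds,
    seed: int = 0,
    n_initial: int | None = None,
    max_proposals: int = 100,
    no_improve_limit: int = 10,
    ei_tol: float = 1e-9,
    improvement_tol: float = 1e-12,
) -> EPSGOResult:
    """Global box-constrained minimization with a GP surrogate and EI sampling.

    A Latin-hypercube design of 10 points per dimension seeds the surrogate;
    each round refits the GP and evaluates the objective at the EI-maximizing
    point (multi-start local search over 100 random candidates). The search
    stops when the best observed value has not improved for
    ``no_improve_limit`` consecutive proposals, when the maximal EI falls
    below ``ei_tol``, or at ``max_proposals``. Exact ties in the objective are
    resolved toward the lexicographically larger point.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    dims = bounds.shape[0]
    if np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("bounds must satisfy low <= high")
    rng = np.random.default_rng(seed)

    if np.all(bounds[:, 1] == bounds[:, 0]):
        point = bounds[:, 0].copy()
        value = float(objective(point))
        return EPSGOResult(point, value, point[None, :], np.array([value]), 1, "degenerate-bounds")

    span = bounds[:, 1] - bounds[:, 0]
    n_initial = n_initial or 10 * dims
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    points = bounds[:, 0] + sampler.random(n_initial) * span
    values = np.array([float(objective(x)) for x in points])

    best_idx = 0
    for i in range(1, len(values)):
        if _prefer(points[i], values[i], points[best_idx], values[best_idx]):
            best_idx = i
    best_point, best_value = points[best_idx].copy(), values[best_idx]

    stopped_by = "max-proposals"
    ei_trace: list[float] = []
    since_improve = 0
    for _ in range(max_proposals):
        surrogate = SurrogateModel(bounds, seed=seed).fit(points, values)
        cand = bounds[:, 0] + rng.random((100, dims)) * span
        ei = np.atleast_1d(expected_improvement(surrogate, cand, best_value))
        order = np.argsort(ei)[::-1]
        x_best, ei_best = cand[order[0]], ei[order[0]]
        for start in cand[order[:5]]:
            res = minimize(
                lambda x: -float(expected_improvement(surrogate, x, best_value)),
                start,
                method="L-BFGS-B",
                bounds=bounds,
            )
            if -res.fun > ei_best:
                x_best, ei_best = np.clip(res.x, bounds[:, 0], bounds[:, 1]), -res.fun
        ei_trace.append(float(ei_best))
        if ei_best < ei_tol:
            stopped_by = "ei-tolerance"
            break
        # avoid re-evaluating an already-visited point
        if np.min(np.linalg.norm(points - x_best, axis=1)) < 1e-10:
            x_best = bounds[:, 0] + rng.random(dims) * span
        value = float(objective(x_best))
        points = np.vstack([points, x_best])
        values = np.append(values, value)
        if best_value - value > improvement_tol:
            best_point, best_value = x_best.copy(), value
            since_improve = 0
        else:
            if _prefer(x_best, value, best_point, best_value):
                best_point = x_best.copy()
            since_improve += 1
            if since_improve >= no_improve_limit:
                stopped_by = "no-improvement"
                break

    return EPSGOResult(
        best_point=best_point,
        best_value=best_value,
        points=points,
        values=values,
        n_evals=len(values),
        stopped_by=stopped_by,
        ei_trace=ei_trace,
    )


# ---------------------------------------------------------------------------
# tuning front end for the SVM families


_ONE_DIM = {"ridge", "lasso", "scad"}
_TWO_DIM = {"elastic_net", "elastic_scad"}


@dataclass
class TuningResult:
    family: str
    best_spec: PenaltySpec
    best_cv_error: float
    evaluations: list  # (params dict, mean error, per-fold errors)
    n_evals: int

    def trace_frame(self):
        """Search trace as a pandas DataFrame (exportable as delimited table)."""
        import pandas as pd

        rows = []
        for params, mean_err, fold_errs in self.evaluations:
            row = dict(params)
            row["mean_cv_error"] = mean_err
            for j, e in enumerate(fold_errs):
                row[f"fold{j}_error"] = e
            rows.append(row)
        return pd.DataFrame(rows)


def _spec_from_point(family: str, theta: np.ndarray, a: float) -> PenaltySpec:
    theta = np.atleast_1d(theta)
    if family == "ridge":
        return PenaltySpec("ridge", C=float(2.0 ** theta[0]))
    if family in ("lasso", "scad"):
        return PenaltySpec(family, lambda1=float(2.0 ** theta[0]), a=a)
    return PenaltySpec(
        family, lambda1=float(2.0 ** theta[0]), lambda2=float(2.0 ** theta[1]), a=a
    )


def tune_parameters(
    data: Dataset,
    family: str,
    k: int = 5,
    seed: int = 0,
    bounds_log2: tuple[float, float] = (-10.0, 10.0),
    method: str = "epsgo",
    a: float = 3.7,
    grid_points_per_dim: int = 11,
    **epsgo_kwargs,
) -> TuningResult:
    """Tune a penalty family by stratified k-fold CV over the log2-scaled box.

    One-dimensional search for ridge (cost C) and lasso/scad (lambda1);
    two-dimensional for the elastic families (lambda1, lambda2). The fold
    split is fixed once so every candidate is scored on identical folds, and
    the L2-SVM start point of the iterative solvers is precomputed per fold.
    """
    from .solvers import fit, fit_elastic_net_svm, fit_l2_svm, fit_lqa

    if family not in _ONE_DIM | _TWO_DIM:
        raise ValueError(f"unknown family {family!r}")
    dims = 1 if family in _ONE_DIM else 2
    plan = stratified_kfold(data.y, k, seed)

    warm: dict[int, tuple[float, np.ndarray]] = {}
    if family in ("scad", "elastic_scad", "elastic_net"):
        for j, (train, _) in enumerate(plan.folds()):
            l2 = fit_l2_svm(data.subset(train), C=1.0)
            warm[j] = (l2.model.b, l2.model.w)

    evaluations = []

    def solver_for(spec: PenaltySpec):
        def _solve(sub: Dataset) -> FitResult:
            if spec.family in ("scad", "elastic_scad"):
                init = warm.get(_fold_of(sub))
                return fit_lqa(sub, spec, init=init)
            if spec.family == "elastic_net":
                init = warm.get(_fold_of(sub))
                return fit_elastic_net_svm(sub, spec.lambda1, spec.lambda2, init=init)
            return fit(sub, spec)

        return _solve

    def _fold_of(sub: Dataset):
        # recover which fold's training half this is; None disables warm start
        for j, (train, _) in enumerate(plan.folds()):
            if sub.n_samples == train.size and sub.sample_ids == [
                data.sample_ids[i] for i in train
            ]:
                return j
        return None

    def objective(theta: np.ndarray) -> float:
        spec = _spec_from_point(family, theta, a)
        cv = cv_error(data, solver_for(spec), plan)
        params = {"lambda1": spec.lambda1, "lambda2": spec.lambda2, "C": spec.C}
        evaluations.append((params, cv.mean_error, cv.fold_errors))
        return cv.mean_error

    lo, hi = bounds_log2
    bounds = np.array([[lo, hi]] * dims)
    if method == "epsgo":
        result = epsgo_search(objective, bounds, seed=seed, **epsgo_kwargs)
        best_theta, best_value = result.best_point, result.best_value
    elif method == "grid":
        axes = [np.linspace(lo, hi, grid_points_per_dim)] * dims
        mesh = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
        best_theta, best_value = None, math.inf
        for theta in mesh:
            value = objective(theta)
            if best_theta is None or _prefer(theta, value, best_theta, best_value):
                best_theta, best_value = theta, value
    else:
        raise ValueError("method must be 'epsgo' or 'grid'")

    return TuningResult(
        family=family,
        best_spec=_spec_from_point(family, best_theta, a),
        best_cv_error=float(best_value),
        evaluations=evaluations,
        n_evals=len(evaluations),
    )
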