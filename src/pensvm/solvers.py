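"""Linear SVM solvers for each penalty family.

All penalized solvers minimize the "loss + penalty" objective

    A(b, w) = (1/n) sum_i [1 - y_i (w.x_i + b)]_+  +  pen(w)

with the hinge loss normalized by the sample size so that tuning-parameter
ranges are comparable across n. The plain soft-margin (ridge) SVM is kept in
its cost form  1/2 ||w||^2 + C sum_i xi_i  and solved through libsvm.

Solver map
----------
ridge         -> `fit_l2_svm`     (libsvm dual, no feature selection)
lasso         -> `fit_l1_svm`     (exact linear program, HiGHS)
scad          -> `fit_lqa`        (iterative local quadratic approximation)
elastic_scad  -> `fit_lqa`
elastic_net   -> `fit_elastic_net_svm` (same IRLS engine; convex objective)

plus `rfe_svm`, the recursive-feature-elimination baseline on top of the L2
SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.svm import SVC

from .core import (
    REMOVAL_THRESHOLD,
    Dataset,
    FitResult,
    LinearModel,
    PenaltySpec,
)
from .penalties import ZERO_FLOOR, lqa_penalty_weight, penalty_value

#: Margin residuals |1 - y f| below this floor are clamped when forming hinge
#: weights, capping the influence of samples lying exactly on the margin.
HINGE_FLOOR = 1e-4

__all__ = [
    "fit_l2_svm",
    "fit_l1_svm",
    "fit_lqa",
    "fit_elastic_net_svm",
    "fit",
    "rfe_svm",
    "halving_schedule",
    "hinge_loss",
    "penalized_objective",
    "l2_primal_objective",
    "LQAState",
    "build_lqa_system",
    "LQAControl",
    "RFEResult",
]


# ---------------------------------------------------------------------------
# objectives


def hinge_loss(y: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-sample hinge loss [1 - y f]_+."""
    return np.maximum(1.0 - y * f, 0.0)


def penalized_objective(data: Dataset, w: np.ndarray, b: float, spec: PenaltySpec) -> float:
    """A(b, w) = mean hinge + pen(w) for any penalty family."""
    f = data.X @ w + b
    return float(hinge_loss(data.y, f).mean() + penalty_value(spec, w).total)


def l2_primal_objective(data: Dataset, w: np.ndarray, b: float, C: float) -> float:
    """Soft-margin primal objective 1/2 ||w||^2 + C sum xi."""
    f = data.X @ w + b
    return float(0.5 * w @ w + C * hinge_loss(data.y, f).sum())


# ---------------------------------------------------------------------------
# L2 (ridge) SVM


def fit_l2_svm(data: Dataset, C: float = 1.0) -> FitResult:
    """Soft-margin linear SVM (no feature selection).

    Solved in the dual through libsvm; the coefficient vector is recovered as
    w = sum_{i in S} alpha_i y_i x_i over the support set S and the intercept
    is averaged over the support-vector conditions for numerical stability.
    The ridge penalty shrinks but never zeroes coefficients, so the active set
    is all p features.
    """
    data.require_both_classes()
    if C <= 0:
        raise ValueError("C must be positive")
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(data.X, data.y)
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    alpha = np.zeros(data.n_samples)
    # dual_coef_ stores y_i * alpha_i for the support vectors
    alpha[svc.support_] = np.abs(svc.dual_coef_.ravel())
    model = LinearModel(
        w=w,
        b=b,
        penalty=PenaltySpec("ridge", C=C),
        active_set=np.arange(data.n_features),
        meta={
            "solver": "libsvm",
            "converged": True,
            "iterations": int(svc.n_iter_[0]),
            "alpha": alpha,
            "support": svc.support_.copy(),
        },
    )
    return FitResult(model=model, objective_trace=[l2_primal_objective(data, w, b, C)])


# ---------------------------------------------------------------------------
# L1 SVM as an exact linear program


def fit_l1_svm(
    data: Dataset,
    lambda1: float,
    removal_threshold: float = REMOVAL_THRESHOLD,
) -> FitResult:
    """L1-penalized SVM: minimize (1/n) sum hinge + lambda1 ||w||_1.

    The problem is linearized exactly with split coefficients w = u - v,
    a free intercept b = b+ - b- and hinge slacks xi, then solved by HiGHS.
    Coefficients below the removal threshold are zeroed.
    """
    data.require_both_classes()
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    n, p = data.X.shape
    yX = data.y[:, None] * data.X
    # variables: u (p), v (p), b+, b-, xi (n)
    c = np.concatenate([np.full(2 * p, lambda1), [0.0, 0.0], np.full(n, 1.0 / n)])
    A_ub = np.hstack([-yX, yX, -data.y[:, None], data.y[:, None], -np.eye(n)])
    b_ub = -np.ones(n)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - formulation is always feasible
        raise RuntimeError(f"L1 SVM linear program failed: {res.message}")
    w = res.x[:p] - res.x[p : 2 * p]
    b = float(res.x[2 * p] - res.x[2 * p + 1])
    w[np.abs(w) < removal_threshold] = 0.0
    spec = PenaltySpec("lasso", lambda1=lambda1)
    model = LinearModel(
        w=w,
        b=b,
        penalty=spec,
        meta={"solver": "linprog-highs", "converged": True, "lp_objective": float(res.fun)},
    )
    return FitResult(model=model, objective_trace=[penalized_objective(data, w, b, spec)])


# ---------------------------------------------------------------------------
# LQA engine (SCAD, Elastic SCAD; also Elastic Net via convex majorization)


@dataclass
class LQAControl:
    """Tolerances of the iterative LQA/IRLS solver."""

    tol: float = 1e-4  # sup-norm change of (b, w) declaring convergence
    max_iter: int = 200
    removal_threshold: float = REMOVAL_THRESHOLD
    zero_floor: float = ZERO_FLOOR  # floor of the penalty-weight denominator
    hinge_floor: float = HINGE_FLOOR  # floor of the margin-residual denominator
    init_C: float = 1.0  # cost of the L2 SVM initializer


@dataclass
class LQAState:
    """One expansion point of the local quadratic approximation."""

    b0: float
    w0: np.ndarray  # full-length coefficient vector (zeros off the active set)
    active: np.ndarray  # indices of features still in the model
    hinge_weights: np.ndarray = field(default=None)  # per-sample s_i >= 0
    penalty_weights: np.ndarray = field(default=None)  # per-active-feature q_j >= 0
    iteration: int = 0


def _compute_weights(
    data: Dataset,
    state: LQAState,
    spec: PenaltySpec,
    zero_floor: float = ZERO_FLOOR,
    hinge_floor: float = HINGE_FLOOR,
) -> None:
    """Fill the hinge and penalty weights of an LQA state in place.

    The hinge is rewritten as [m]_+ = (|m| + m)/2 with margin residual
    m = 1 - y f(x), and |m| is majorized by m^2/(2|m0|) + |m0|/2, so sample i
    contributes  s_i (1 - y_i f)^2 + (1 - y_i f)/2 + const  with weight
    s_i = 1 / (4 max(|m0_i|, hinge_floor)). This is a global majorant of the
    hinge that matches its value and gradient at the expansion point wherever
    |m0_i| exceeds the floor. The floor caps the weight of samples sitting on
    the margin (the L2 start point puts its support vectors exactly there),
    which would otherwise pin the iterate in place.
    """
    f0 = data.X[:, state.active] @ state.w0[state.active] + state.b0
    m = 1.0 - data.y * f0
    state.hinge_weights = 1.0 / (4.0 * np.maximum(np.abs(m), hinge_floor))
    state.penalty_weights = np.atleast_1d(
        lqa_penalty_weight(spec, state.w0[state.active], zero_floor)
    )


def build_lqa_system(
    data: Dataset, state: LQAState, spec: PenaltySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Normal equations of the local quadratic model over (b, w_active).

    With the intercept-augmented design Xt = [1, X_active], hinge-weight matrix
    W = diag(s_i) and penalty block P = diag(0, q_j), minimizing the local
    quadratic  (1/n) sum_i [s_i (y_i - f_i)^2 + (1 - y_i f_i)/2] + sum_j q_j w_j^2
    is equivalent to solving

        (Xt' W Xt + n P) c = Xt' W z,    z_i = y_i (1 + 1/(4 s_i)),

    for c = (b, w_active); the targets z fold the linear hinge term into the
    weighted regression.
    """
    if state.active.size == 0:
        raise ValueError("active set is empty")
    if state.hinge_weights is None or state.penalty_weights is None:
        _compute_weights(data, state, spec)
    n = data.n_samples
    Xt = np.hstack([np.ones((n, 1)), data.X[:, state.active]])
    sw = state.hinge_weights
    A = (Xt * sw[:, None]).T @ Xt
    A[1:, 1:] += n * np.diag(state.penalty_weights)
    rhs = Xt.T @ (sw * data.y + data.y / 4.0)
    return A, rhs


def _solve_lqa_system(A: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve the (symmetric PSD) LQA system, adding diagonal jitter on the
    coefficient block if it is numerically singular."""
    try:
        c = np.linalg.solve(A, rhs)
        if np.all(np.isfinite(c)):
            return c, False
    except np.linalg.LinAlgError:
        pass
    Aj = A.copy()
    Aj[np.arange(1, A.shape[0]), np.arange(1, A.shape[0])] += 1e-8
    return np.linalg.lstsq(Aj, rhs, rcond=None)[0], True


def _majority_intercept(y: np.ndarray) -> float:
    """Mean-hinge-minimizing intercept of an intercept-only model.

    (1/n) sum [1 - y b]_+ is piecewise linear and minimized at b = +1 when the
    positive class is at least as frequent, else at b = -1.
    """
    return 1.0 if np.sum(y == 1) >= np.sum(y == -1) else -1.0


def fit_lqa(
    data: Dataset,
    spec: PenaltySpec,
    control: LQAControl | None = None,
    init: tuple[float, np.ndarray] | None = None,
) -> FitResult:
    """Penalized SVM via iterative local quadratic approximation.

    Intended for the non-convex families ``scad`` and ``elastic_scad`` (the
    convex ``lasso``/``elastic_net`` objectives are also accepted, in which
    case the scheme is a plain majorize-minimize iteration converging to the
    global minimum).

    Each iteration (i) stores the expansion point, (ii) recomputes hinge and
    penalty weights there, (iii) solves the resulting linear system and (iv)
    permanently removes features whose coefficient falls below the removal
    threshold. The start point is a standard L2 SVM fit (cost ``control.init_C``)
    unless ``init=(b0, w0)`` is given. Non-convergence within ``max_iter`` is
    reported through the model's ``converged`` flag, not raised.
    """
    data.require_both_classes()
    if spec.family not in ("scad", "elastic_scad", "lasso", "elastic_net"):
        raise ValueError(f"fit_lqa does not handle family {spec.family!r}")
    control = control or LQAControl()
    p = data.n_features

    if init is None:
        l2 = fit_l2_svm(data, C=control.init_C)
        b0, w0 = l2.model.b, l2.model.w.copy()
    else:
        b0, w0 = float(init[0]), np.asarray(init[1], dtype=float).copy()

    active = np.arange(p)
    trace = [penalized_objective(data, w0, b0, spec)]
    removal_steps: list[int] = []  # trace indices whose transition removed features
    converged = False
    jitter_used = False
    it = 0
    for it in range(1, control.max_iter + 1):
        # drop coefficients that have shrunk below the removal threshold
        keep = np.abs(w0[active]) >= control.removal_threshold
        removed_now = not np.all(keep)
        if removed_now:
            w0[active[~keep]] = 0.0
            active = active[keep]
        if active.size == 0:
            b0 = _majority_intercept(data.y)
            w0 = np.zeros(p)
            converged = True
            trace.append(penalized_objective(data, w0, b0, spec))
            removal_steps.append(len(trace) - 1)
            break

        state = LQAState(b0=b0, w0=w0, active=active, iteration=it)
        _compute_weights(data, state, spec, control.zero_floor, control.hinge_floor)
        A, rhs = build_lqa_system(data, state, spec)
        c, jit = _solve_lqa_system(A, rhs)
        jitter_used = jitter_used or jit
        b1 = float(c[0])
        w1 = np.zeros(p)
        w1[active] = c[1:]

        # The quadratic model shares the objective's gradient at the expansion
        # point, so its minimizer defines a descent direction; the hinge's zero
        # branch is not globally majorized, hence a full step may overshoot.
        # Backtrack until the true objective does not increase.
        obj0 = penalized_objective(data, w0, b0, spec)
        t = 1.0
        while t > 2.0**-20:
            bt = b0 + t * (b1 - b0)
            wt = w0 + t * (w1 - w0)
            if penalized_objective(data, wt, bt, spec) <= obj0 + 1e-12:
                break
            t /= 2.0
        b1 = b0 + t * (b1 - b0)
        w1 = w0 + t * (w1 - w0)

        step = max(abs(b1 - b0), float(np.max(np.abs(w1 - w0))))
        b0, w0 = b1, w1
        trace.append(penalized_objective(data, w0, b0, spec))
        if removed_now:
            removal_steps.append(len(trace) - 1)
        if step < control.tol and not removed_now:
            converged = True
            break

    # final clean-up at the removal threshold
    w0[np.abs(w0) < control.removal_threshold] = 0.0
    model = LinearModel(
        w=w0,
        b=b0,
        penalty=spec,
        meta={
            "solver": "lqa",
            "converged": converged,
            "iterations": it,
            "jitter_used": jitter_used,
            "removal_steps": removal_steps,
        },
    )
    trace.append(penalized_objective(data, model.w, model.b, spec))
    removal_steps.append(len(trace) - 1)
    return FitResult(model=model, objective_trace=trace)


def fit_elastic_net_svm(
    data: Dataset,
    lambda1: float,
    lambda2: float,
    control: LQAControl | None = None,
    init: tuple[float, np.ndarray] | None = None,
) -> FitResult:
    """Elastic Net SVM: (1/n) sum hinge + lambda1 ||w||_1 + lambda2 ||w||_2^2.

    With lambda2 = 0 the objective is definitionally the L1 SVM and the exact
    linear program is used. Otherwise the convex objective is minimized by
    iteratively reweighted least squares (the same majorization engine as the
    SCAD solvers, with the L1 majorant |w| <= w^2/(2|w0|) + |w0|/2), run at a
    tight tolerance; the zeroing threshold is applied as in `fit_l1_svm`.
    """
    if lambda1 < 0 or lambda2 < 0 or lambda1 + lambda2 == 0:
        raise ValueError("need lambda1, lambda2 >= 0 with lambda1 + lambda2 > 0")
    if lambda2 == 0.0:
        return fit_l1_svm(data, lambda1)
    spec = PenaltySpec("elastic_net", lambda1=lambda1, lambda2=lambda2)
    if control is None:
        # convex problem: iterate tighter, prune only clearly-dead coefficients
        control = LQAControl(tol=1e-6, max_iter=300, removal_threshold=1e-6)
    res = fit_lqa(data, spec, control=control, init=init)
    w = res.model.w
    w[np.abs(w) < REMOVAL_THRESHOLD] = 0.0
    model = LinearModel(w=w, b=res.model.b, penalty=spec, meta=res.model.meta)
    res.objective_trace.append(penalized_objective(data, model.w, model.b, spec))
    return FitResult(model=model, objective_trace=res.objective_trace)


def fit(data: Dataset, spec: PenaltySpec, **kwargs) -> FitResult:
    """Dispatch to the solver of a penalty family."""
    if spec.family == "ridge":
        return fit_l2_svm(data, C=spec.C, **kwargs)
    if spec.family == "lasso":
        return fit_l1_svm(data, lambda1=spec.lambda1, **kwargs)
    if spec.family == "elastic_net":
        return fit_elastic_net_svm(data, spec.lambda1, spec.lambda2, **kwargs)
    return fit_lqa(data, spec, **kwargs)


# ---------------------------------------------------------------------------
# recursive feature elimination baseline


def halving_schedule(p: int) -> list[int]:
    """Subset sizes visited by RFE: p, then the powers of two below p down to 1.

    Starting the halving from the largest power of two below p reproduces the
    conventional 2^k candidate sizes (e.g. 256 appears for p = 4919).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if p == 1:
        return [1]
    sizes = [p]
    s = 1 << ((p - 1).bit_length() - 1)  # largest power of two < p
    while s >= 1:
        sizes.append(s)
        s //= 2
    return sizes


@dataclass
class RFEResult:
    sizes: list[int]
    feature_sets: list[np.ndarray]
    cv_errors: list[float]
    best_size: int
    best_features: np.ndarray


def rfe_svm(data: Dataset, C: float, plan, cv_error_fn=None) -> RFEResult:
    """Recursive feature elimination around the L2 SVM.

    Features are ranked by |w_j| of an L2 SVM fit on the full training data and
    the lowest-ranked ones are discarded down to the next scheduled size; the
    stratified-CV error of an L2 SVM restricted to each retained set picks the
    winning size. Ties in |w_j| are broken by feature index (lower index
    eliminated first) for determinism.
    """
    from .model_selection import cv_error  # local import to avoid a cycle

    if data.n_features < 2:
        raise ValueError("RFE needs at least 2 features")
    sizes = halving_schedule(data.n_features)
    current = np.arange(data.n_features)
    feature_sets, errors = [], []
    def _restrict(idx: np.ndarray) -> Dataset:
        return Dataset(
            data.X[:, idx], data.y,
            [data.feature_ids[j] for j in idx], list(data.sample_ids),
        )

    for size in sizes:
        if size < current.size:
            res = fit_l2_svm(_restrict(current), C=C)
            rank = np.lexsort((current, np.abs(res.model.w)))  # ascending |w|, ties by index
            current = np.sort(current[rank[current.size - size:]])
        feature_sets.append(current.copy())
        sub = _restrict(current)
        cv = cv_error(sub, lambda d: fit_l2_svm(d, C=C), plan)
        errors.append(cv.mean_error)
    best = int(np.argmin(errors))
    return RFEResult(
        sizes=sizes,
        feature_sets=feature_sets,
        cv_errors=errors,
        best_size=sizes[best],
        best_features=feature_sets[best],
    )
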