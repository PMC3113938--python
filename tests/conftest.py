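"""Shared fixtures: random problem instances, convex-programming oracles and
the (expensive, session-scoped) scaled-down simulation study."""

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import minimize

from pensvm.core import Dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_dataset(n: int, p: int, seed: int) -> Dataset:
    """Random Gaussian instance with both classes guaranteed present."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[0], y[1] = 1.0, -1.0
    return Dataset(X, y)


@pytest.fixture
def toy_separable():
    """Two symmetric points on the first axis: w ~ (1, 0), b = 0."""
    return Dataset(np.array([[-1.0, 0.0], [1.0, 0.0]]), np.array([-1.0, 1.0]))


# ---------------------------------------------------------------------------
# independent convex-programming oracles (SLSQP on split-variable forms)


def oracle_penalized_objective(data: Dataset, lambda1: float, lambda2: float) -> float:
    """Generic convex solve of (1/n) sum hinge + lambda1||w||_1 + lambda2||w||_2^2.

    Split variables w = u - v with u, v >= 0, hinge slacks xi, free intercept.
    Independent of the package's LP/IRLS solution paths.
    """
    n, p = data.X.shape

    def obj(z):
        u, v, xi = z[:p], z[p : 2 * p], z[2 * p + 1 :]
        w = u - v
        return xi.mean() + lambda1 * (u + v).sum() + lambda2 * float(w @ w)

    def feas(z):
        w, b = z[:p] - z[p : 2 * p], z[2 * p]
        return z[2 * p + 1 :] - (1.0 - data.y * (data.X @ w + b))

    bounds = [(0, None)] * (2 * p) + [(None, None)] + [(0, None)] * n
    z0 = np.zeros(2 * p + 1 + n)
    z0[2 * p + 1 :] = 1.0
    res = minimize(
        obj, z0, method="SLSQP", bounds=bounds,
        constraints=[{"type": "ineq", "fun": feas}],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    assert res.success or res.fun is not None
    return float(res.fun)


def oracle_l2_objective(data: Dataset, C: float) -> float:
    """Generic convex solve of the soft-margin primal 1/2||w||^2 + C sum xi."""
    n, p = data.X.shape

    def obj(z):
        w, xi = z[:p], z[p + 1 :]
        return 0.5 * float(w @ w) + C * xi.sum()

    def feas(z):
        w, b = z[:p], z[p]
        return z[p + 1 :] - (1.0 - data.y * (data.X @ w + b))

    bounds = [(None, None)] * (p + 1) + [(0, None)] * n
    z0 = np.zeros(p + 1 + n)
    z0[p + 1 :] = 1.0
    res = minimize(
        obj, z0, method="SLSQP", bounds=bounds,
        constraints=[{"type": "ineq", "fun": feas}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return float(res.fun)


def polish_active_set(data: Dataset, result, spec, n_starts: int = 5, scale: float = 0.05):
    """Derivative-free multi-start polish of the penalized objective over the
    fitted model's active set; returns the best objective found."""
    from pensvm.solvers import penalized_objective

    act = result.model.active_set
    rng = np.random.default_rng(0)

    def obj(z):
        w = np.zeros(data.n_features)
        w[act] = z[1:]
        return penalized_objective(data, w, float(z[0]), spec)

    z0 = np.concatenate([[result.model.b], result.model.w[act]])
    best = obj(z0)
    for s in range(n_starts):
        start = z0 if s == 0 else z0 + rng.normal(0.0, scale, z0.shape)
        res = minimize(obj, start, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11})
        best = min(best, float(res.fun))
    return best


# ---------------------------------------------------------------------------
# scaled-down simulation study (shared by the acceptance suite and the
# sparsity-ordering property); ~10 minutes, computed once per session


@pytest.fixture(scope="session")
def scaled_study():
    from pensvm.simulation import SimulationDesign, run_study

    design = SimulationDesign(p=200, r=10, n_train=200, n_test=200, beta_magnitude=0.5)
    summary = run_study(
        design,
        ["ridge", "lasso", "scad", "elastic_net", "elastic_scad"],
        runs=10,
        k=5,
        seed=1,
    )
    return summary
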