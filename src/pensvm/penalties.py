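"""Penalty functions, derivatives and local-quadratic-approximation weights.

The SCAD penalty is a quadratic spline with knots at lambda1 and a*lambda1:
linear (L1-like) for small coefficients, quadratic in between, constant for
large ones. The Elastic SCAD penalty adds lambda2 * w^2 to SCAD; the Elastic
Net combines lambda1 * |w| with lambda2 * w^2.

The LQA solver replaces each penalty term by a quadratic majorant
q_j * w_j^2 + const matched in value and gradient at the expansion point w0_j;
`lqa_penalty_weight` computes q_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PenaltySpec

#: Floor for the |w0| denominator of LQA weights; distinct from the 1e-4
#: feature-removal threshold so that shrinking coefficients do not blow up q_j.
ZERO_FLOOR = 1e-8


def _check_scad_args(lambda1: float, a: float) -> None:
    if lambda1 <= 0:
        raise ValueError("SCAD requires lambda1 > 0")
    if a <= 2:
        raise ValueError("SCAD requires a > 2")


def scad_value(w_abs, lambda1: float, a: float = 3.7):
    """SCAD penalty of a coefficient magnitude.

    Piecewise: lambda1*|w| up to the first knot, a quadratic blend between the
    knots, and the constant (a+1)*lambda1^2/2 beyond a*lambda1. Accepts scalars
    or arrays.
    """
    _check_scad_args(lambda1, a)
    w_abs = np.asarray(w_abs, dtype=float)
    if np.any(w_abs < 0):
        raise ValueError("w_abs must be nonnegative")
    lin = lambda1 * w_abs
    quad = -(w_abs**2 - 2.0 * a * lambda1 * w_abs + lambda1**2) / (2.0 * (a - 1.0))
    const = (a + 1.0) * lambda1**2 / 2.0
    out = np.where(w_abs <= lambda1, lin, np.where(w_abs <= a * lambda1, quad, const))
    return out.item() if out.ndim == 0 else out


def scad_derivative(w_abs, lambda1: float, a: float = 3.7):
    """First derivative of the SCAD penalty w.r.t. the magnitude.

    lambda1 on the linear piece, (a*lambda1 - |w|)/(a-1) between the knots,
    0 beyond the second knot; continuous at both knots.
    """
    _check_scad_args(lambda1, a)
    w_abs = np.asarray(w_abs, dtype=float)
    if np.any(w_abs < 0):
        raise ValueError("w_abs must be nonnegative")
    mid = (a * lambda1 - w_abs) / (a - 1.0)
    out = np.where(w_abs <= lambda1, lambda1, np.where(w_abs <= a * lambda1, mid, 0.0))
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class PenaltyEvaluation:
    total: float
    per_feature: np.ndarray


def penalty_value(spec: PenaltySpec, w: np.ndarray) -> PenaltyEvaluation:
    """Evaluate pen(w) for any supported family.

    ridge: lambda2 * sum w^2        lasso: lambda1 * sum |w|
    scad:  sum scad(|w|)            elastic_net: lasso + ridge terms
    elastic_scad: scad + ridge terms
    """
    w = np.asarray(w, dtype=float)
    w_abs = np.abs(w)
    if spec.family == "ridge":
        per = spec.lambda2 * w**2
    elif spec.family == "lasso":
        per = spec.lambda1 * w_abs
    elif spec.family == "scad":
        per = np.asarray(scad_value(w_abs, spec.lambda1, spec.a))
    elif spec.family == "elastic_net":
        per = spec.lambda1 * w_abs + spec.lambda2 * w**2
    elif spec.family == "elastic_scad":
        per = np.asarray(scad_value(w_abs, spec.lambda1, spec.a)) + spec.lambda2 * w**2
    else:  # pragma: no cover - guarded by PenaltySpec
        raise ValueError(f"unknown family {spec.family!r}")
    per = np.atleast_1d(per)
    return PenaltyEvaluation(total=float(per.sum()), per_feature=per)


def sparsity_derivative(spec: PenaltySpec, w_abs) -> np.ndarray:
    """Derivative of the non-ridge part of the penalty w.r.t. |w|."""
    w_abs = np.asarray(w_abs, dtype=float)
    if spec.family in ("scad", "elastic_scad"):
        return np.asarray(scad_derivative(w_abs, spec.lambda1, spec.a))
    if spec.family in ("lasso", "elastic_net"):
        return np.full_like(w_abs, spec.lambda1)
    if spec.family == "ridge":
        return np.zeros_like(w_abs)
    raise ValueError(f"unknown family {spec.family!r}")  # pragma: no cover


def lqa_penalty_weight(spec: PenaltySpec, w0, zero_floor: float = ZERO_FLOOR):
    """Quadratic weight q_j of the penalty majorant at expansion point w0_j.

    q_j = pen'(|w0_j|) / (2 * max(|w0_j|, zero_floor)) + lambda2, where pen' is
    the derivative of the sparsity part (SCAD or L1) and lambda2 enters for the
    elastic families. The majorant Q(w) = pen(|w0|) + q_j (w^2 - w0^2) matches
    the penalty in value and gradient at w0.
    """
    w0_abs = np.abs(np.asarray(w0, dtype=float))
    deriv = sparsity_derivative(spec, w0_abs)
    lam2 = spec.lambda2 if spec.family in ("elastic_net", "elastic_scad", "ridge") else 0.0
    out = deriv / (2.0 * np.maximum(w0_abs, zero_floor)) + lam2
    return out.item() if out.ndim == 0 else out
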