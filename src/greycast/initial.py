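"""Initial-condition optimization for the GM(1,1) time-response function.

The classic GM(1,1) anchors its time-response function at the first
observation, C = x0(1). That anchor is arbitrary: least squares fixed
(a, b) without reference to x0(1), and forcing the fitted curve through the
first point can cost simulation accuracy everywhere else. The optimized
variant instead chooses C to minimize the sum of squared *relative*
simulation errors

    J(C) = sum_k r_k(C)^2,
    r_k(C) = (x0_hat(k; C) - x0(k)) / x0(k)

where for k >= 2 the restored value is x0_hat(k) = phi_k (C - b/a) with
phi_k = (1 - e^a) e^(-a(k-1)). Every r_k is affine in C, so J is a strictly
convex quadratic with the unique closed-form minimizer

    C* = - sum_k alpha_k beta_k / sum_k alpha_k^2,
    r_k(C) = alpha_k C + beta_k.

The first-year term is ambiguous: the restoration formula has no natural
k = 1 value (first differencing leaves x1_hat(1) = C itself). Three
conventions are implemented, selected by ``objective_k1``:

- ``ratio_to_first`` (default): r_1 = (C - x0(1)) / x0(1), i.e. the reported
  first fitted value is C itself;
- ``restored_formula``: r_1 uses phi_1 (C - b/a), extending the k >= 2
  formula down to k = 1;
- ``exclude``: the sum runs over k = 2..n only.

A bounded scalar minimizer over the objective serves as an independent
brute-force check of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ZeroObservation
from .sequences import AnnualSeries

__all__ = [
    "InitialValue",
    "objective",
    "optimize_initial",
    "classic_initial",
    "brute_force_initial",
]

_K1_VARIANTS = ("ratio_to_first", "restored_formula", "exclude")
_A_EPS = 1e-12


@dataclass(frozen=True)
class InitialValue:
    """Resolved initial condition of the time-response function.

    Attributes
    ----------
    C : float
        Accumulated-scale initial condition.
    variant : str
        ``"classic"`` (C = first observation) or ``"optimized"``.
    objective_value : float
        Sum of squared relative simulation errors at C.
    objective_k1 : str
        First-year convention used in the objective.
    """

    C: float
    variant: str
    objective_value: float
    objective_k1: str = "ratio_to_first"


def _check(series: AnnualSeries, objective_k1: str) -> np.ndarray:
    if objective_k1 not in _K1_VARIANTS:
        raise ValueError(
            f"objective_k1 must be one of {_K1_VARIANTS}, got {objective_k1!r}"
        )
    x = series.values
    if np.any(x <= 0):
        raise ZeroObservation(
            f"{series.label}: relative-error objective needs strictly "
            "positive observations"
        )
    return x


def _affine_coeffs(
    a: float, b: float, x: np.ndarray, objective_k1: str
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (alpha_k, beta_k) of the affine residuals r_k = alpha_k C + beta_k."""
    n = len(x)
    k = np.arange(2, n + 1)
    if abs(a) < _A_EPS:
        # a -> 0 limit: restored values are the constant b, independent of C
        phi = np.zeros(n - 1)
        drift = np.full(n - 1, b)
    else:
        phi = (1.0 - np.exp(a)) * np.exp(-a * (k - 1.0))
        drift = -phi * b / a
    alpha = phi / x[1:]
    beta = (drift - x[1:]) / x[1:]
    if objective_k1 == "ratio_to_first":
        alpha = np.concatenate([[1.0 / x[0]], alpha])
        beta = np.concatenate([[-1.0], beta])
    elif objective_k1 == "restored_formula":
        phi1 = -a if abs(a) < _A_EPS else 1.0 - np.exp(a)
        drift1 = b if abs(a) < _A_EPS else -phi1 * b / a
        alpha = np.concatenate([[phi1 / x[0]], alpha])
        beta = np.concatenate([[(drift1 - x[0]) / x[0]], beta])
    return alpha, beta


def objective(
    a: float,
    b: float,
    C: float,
    series: AnnualSeries,
    objective_k1: str = "ratio_to_first",
) -> float:
    """Sum of squared relative simulation errors at initial condition C."""
    x = _check(series, objective_k1)
    alpha, beta = _affine_coeffs(a, b, x, objective_k1)
    return float(np.sum((alpha * C + beta) ** 2))


def classic_initial(
    a: float,
    b: float,
    series: AnnualSeries,
    objective_k1: str = "ratio_to_first",
) -> InitialValue:
    """Classic anchor C = x0(1), with its objective value for comparison."""
    C = float(series.values[0])
    return InitialValue(
        C=C,
        variant="classic",
        objective_value=objective(a, b, C, series, objective_k1),
        objective_k1=objective_k1,
    )


def optimize_initial(
    a: float,
    b: float,
    series: AnnualSeries,
    objective_k1: str = "ratio_to_first",
) -> InitialValue:
    """Closed-form minimizer of the quadratic objective over C.

    With r_k(C) = alpha_k C + beta_k, setting dJ/dC = 2 sum alpha_k (alpha_k
    C + beta_k) = 0 gives C* = -sum(alpha beta) / sum(alpha^2). Degenerate
    case: if every alpha_k is 0 (a -> 0 with the k = 1 term excluded), C has
    no effect on the objective and the classic anchor is returned.
    """
    x = _check(series, objective_k1)
    alpha, beta = _affine_coeffs(a, b, x, objective_k1)
    denom = float(np.sum(alpha**2))
    if denom < 1e-300:
        return classic_initial(a, b, series, objective_k1)
    C = float(-np.sum(alpha * beta) / denom)
    return InitialValue(
        C=C,
        variant="optimized",
        objective_value=float(np.sum((alpha * C + beta) ** 2)),
        objective_k1=objective_k1,
    )


def brute_force_initial(
    a: float,
    b: float,
    series: AnnualSeries,
    objective_k1: str = "ratio_to_first",
    bracket_factor: tuple[float, float] = (0.1, 10.0),
) -> float:
    """1-D bounded minimization of the objective; independent check of the
    closed form.

    Searches C in [lo * x0(1), hi * x0(1)] with scipy's bounded Brent
    method at tight tolerance.
    """
    x1 = float(series.values[0])
    lo, hi = bracket_factor[0] * x1, bracket_factor[1] * x1
    res = minimize_scalar(
        lambda C: objective(a, b, C, series, objective_k1),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
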