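"""Model-adequacy tests for grey simulations.

Two complementary checks grade a fitted GM(1,1) model:

- the *average relative error* (mean of |residual/observed|), a pointwise
  accuracy measure; and
- the *grey absolute correlation degree* eta in (0, 1], a geometric
  closeness measure between the observed and simulated trajectories based
  on the signed areas each sweeps relative to its starting level. eta = 1
  iff the two trajectories are congruent up to a vertical shift.

Both are graded I-IV against conventional critical values (I is best):

    grade              I      II     III    IV
    avg rel. error  <= 0.01   0.05   0.1    0.2
    correlation     >= 0.9    0.8    0.7    0.6
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import LengthMismatch, ZeroObservation

__all__ = [
    "GradeTable",
    "DiagnosticsReport",
    "mean_relative_error",
    "grey_correlation_degree",
    "grade_relative_error",
    "grade_correlation",
    "diagnose",
]


@dataclass(frozen=True)
class GradeTable:
    """Critical values for the two accuracy tests, best grade first."""

    relative_error: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2)
    correlation: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6)
    labels: tuple[str, ...] = ("I", "II", "III", "IV")


DEFAULT_GRADES = GradeTable()


@dataclass(frozen=True)
class DiagnosticsReport:
    mean_relative_error: float
    correlation_degree: float
    grade_relative_error: str
    grade_correlation: str


def mean_relative_error(
    observed: np.ndarray,
    fitted: np.ndarray,
    divisor: str = "n_minus_1",
) -> float:
    """Average absolute relative simulation error.

    Parameters
    ----------
    observed, fitted : arrays of equal length n, observed strictly positive.
    divisor : {"n_minus_1", "n"}
        ``n_minus_1`` (default) averages over k = 2..n, excluding the
        first-year term that is zero by the reporting convention
        fitted[0] = observed[0]; ``n`` averages all n terms.
    """
    observed = np.asarray(observed, float)
    fitted = np.asarray(fitted, float)
    if observed.shape != fitted.shape:
        raise LengthMismatch(
            f"observed ({observed.shape}) and fitted ({fitted.shape}) differ"
        )
    if np.any(observed <= 0):
        raise ZeroObservation("relative errors need strictly positive observations")
    rel = np.abs((observed - fitted) / observed)
    if divisor == "n_minus_1":
        return float(np.mean(rel[1:]))
    if divisor == "n":
        return float(np.mean(rel))
    raise ValueError(f"divisor must be 'n_minus_1' or 'n', got {divisor!r}")


def _s_statistic(v: np.ndarray) -> float:
    """|s| = |sum_{k=2}^{n-1} (v(k) - v(1)) + (v(n) - v(1)) / 2|.

    Trapezoid-style signed area between the trajectory and the horizontal
    line through its first point.
    """
    d = v - v[0]
    return abs(float(np.sum(d[1:-1]) + 0.5 * d[-1]))


def grey_correlation_degree(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Grey absolute correlation degree eta between two equal-length series.

    eta = (1 + |s| + |s_hat|) / (1 + |s| + |s_hat| + |s_hat - s|), where
    |s| and |s_hat| are the area statistics of the observed and fitted
    series and |s_hat - s| is the same statistic of their pointwise
    difference. Always in (0, 1]; equals 1 iff the difference series is
    flat (identical shapes).
    """
    observed = np.asarray(observed, float)
    fitted = np.asarray(fitted, float)
    if observed.shape != fitted.shape:
        raise LengthMismatch(
            f"observed ({observed.shape}) and fitted ({fitted.shape}) differ"
        )
    s = _s_statistic(observed)
    s_hat = _s_statistic(fitted)
    s_diff = _s_statistic(fitted - observed)
    return (1.0 + s + s_hat) / (1.0 + s + s_hat + s_diff)


def _grade(
    value: float, thresholds: tuple[float, ...], labels: tuple[str, ...], ge: bool
) -> str:
    for thr, lab in zip(thresholds, labels):
        if (value >= thr) if ge else (value <= thr):
            return lab
    return "fail"


def grade_relative_error(value: float, table: GradeTable = DEFAULT_GRADES) -> str:
    """Best grade whose critical value c satisfies value <= c; 'fail' if none."""
    return _grade(value, table.relative_error, table.labels, ge=False)


def grade_correlation(value: float, table: GradeTable = DEFAULT_GRADES) -> str:
    """Best grade whose critical value eta0 satisfies value >= eta0; 'fail' if none."""
    return _grade(value, table.correlation, table.labels, ge=True)


def diagnose(
    observed: np.ndarray,
    fitted: np.ndarray,
    divisor: str = "n_minus_1",
    table: GradeTable = DEFAULT_GRADES,
) -> DiagnosticsReport:
    """Run both adequacy tests and grade the results."""
    mre = mean_relative_error(observed, fitted, divisor=divisor)
    eta = grey_correlation_degree(observed, fitted)
    return DiagnosticsReport(
        mean_relative_error=mre,
        correlation_degree=eta,
        grade_relative_error=grade_relative_error(mre, table),
        grade_correlation=grade_correlation(eta, table),
    )
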