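"""Even GM(1,1) grey forecasting model.

The grey model of first order in one variable fits the grey differential
equation

    x0(k) + a * z1(k) = b,        k = 2..n

where ``x0`` is the raw series, ``z1`` the consecutive-neighbour means of
its running partial sums (1-AGO), ``a`` the development coefficient and
``b`` the grey action quantity. ``(a, b)`` are the least-squares solution of
the n-1 stacked equations. The whitenized equation dx1/dt + a*x1 = b has the
time-response solution

    x1_hat(k) = (C - b/a) * exp(-a (k - 1)) + b/a

with initial condition C (classically the first observation; optionally
optimized, see :mod:`greycast.initial`), and fitted/forecast values on the
original scale are recovered by first differencing:

    x0_hat(k) = (1 - e^a) (C - b/a) exp(-a (k - 1)),   k >= 2.

Negative ``a`` means the restored series grows at rate e^(-a) per step,
positive ``a`` means decay. The model is intended for short (n of order
4-10), positive, roughly exponential-trend series.

Usage follows the model/results idiom::

    model = GM11(series)
    res = model.fit(init="optimized")
    res.summary()
    res.forecast(6)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import initial as _initial
from .diagnostics import DiagnosticsReport, diagnose
from .exceptions import HorizonNonPositive, SingularDesign
from .sequences import (
    AnnualSeries,
    ago,
    mean_generation,
    round_display,
    validate,
)

__all__ = ["GM11", "GM11Results", "ForecastResult", "restored_values"]

logger = logging.getLogger(__name__)

#: Below this |a| the model degenerates to constant per-step increments b
#: (the analytic a -> 0 limit); avoids dividing by a.
A_EPS = 1e-12

#: Classic applicability bound: for |a| >= 2 the restored model's sign
#: alternates and GM(1,1) forecasts are meaningless.
A_APPLICABILITY_BOUND = 2.0


def restored_values(a: float, b: float, C: float, k: np.ndarray | int) -> np.ndarray:
    """Restored (original-scale) model value x0_hat(k) for k >= 2.

    Evaluates (1 - e^a)(C - b/a) e^(-a(k-1)); for |a| < 1e-12 the analytic
    limit is the constant b.
    """
    k = np.asarray(k, dtype=float)
    if abs(a) < A_EPS:
        return np.full_like(k, b)
    return (1.0 - np.exp(a)) * (C - b / a) * np.exp(-a * (k - 1.0))


@dataclass(frozen=True)
class ForecastResult:
    """Out-of-sample restored forecasts for k = n+1, n+2, ..."""

    years: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "forecast": self.values})


class GM11:
    """Even GM(1,1) model for a short annual series.

    Parameters
    ----------
    series : AnnualSeries
        Validated non-negative series, n >= 4.

    Notes
    -----
    Construction validates the input and precomputes the 1-AGO and
    consecutive-neighbour mean sequences; :meth:`fit` solves the normal
    equations and resolves the initial condition.
    """

    def __init__(self, series: AnnualSeries):
        self.series = validate(series)
        self.acc = ago(series)
        self.mean_seq = mean_generation(self.acc)
        # regression design: x0(k) = -a z1(k) + b over k = 2..n
        self.response = series.values[1:]
        self.design = np.column_stack(
            [-self.mean_seq.values, np.ones(len(self.mean_seq))]
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column: str,
        year_column: str = "year",
        units: str = "",
        buffered: bool = False,
    ) -> "GM11":
        """Build a model from a (year, value) DataFrame column."""
        d = df.sort_values(year_column)
        series = AnnualSeries(
            label=column,
            start_year=int(d[year_column].iloc[0]),
            values=d[column].to_numpy(dtype=float),
            units=units,
            buffered=buffered,
        )
        return cls(series)

    def fit(
        self,
        init: str = "optimized",
        objective_k1: str = "ratio_to_first",
    ) -> "GM11Results":
        """Estimate (a, b) by least squares and resolve the initial condition.

        Parameters
        ----------
        init : {"optimized", "classic"}
            ``classic`` uses C = x0(1); ``optimized`` minimizes the sum of
            squared relative simulation errors over C.
        objective_k1 : {"ratio_to_first", "restored_formula", "exclude"}
            How the optimizer's objective treats the first-year term (the
            restored formula is ambiguous at k = 1; see
            :func:`greycast.initial.objective`).
        """
        if self.design.shape[0] < 2:
            raise SingularDesign("need at least 2 regression rows (n >= 3)")
        # lstsq on the 2-column design is algebraically the normal equations
        # of the grey regression, solved stably via SVD.
        coef, *_ = np.linalg.lstsq(self.design, self.response, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        if abs(a) >= A_APPLICABILITY_BOUND:
            logger.warning(
                "%s: |a| = %.3f >= 2; GM(1,1) is outside its applicability "
                "range and restored values alternate in sign",
                self.series.label,
                abs(a),
            )
        if init == "classic":
            iv = _initial.classic_initial(a, b, self.series, objective_k1=objective_k1)
        elif init == "optimized":
            iv = _initial.optimize_initial(a, b, self.series, objective_k1=objective_k1)
        else:
            raise ValueError(f"unknown init variant {init!r}")
        return GM11Results(self, a, b, iv)


class GM11Results:
    """Fitted GM(1,1) model: parameters, fitted values, diagnostics, forecasts.

    Attributes
    ----------
    a : float
        Development coefficient (per-step exponential rate).
    b : float
        Grey action quantity (units of the observations).
    init : greycast.initial.InitialValue
        Resolved initial condition C of the time-response function.
    """

    def __init__(self, model: GM11, a: float, b: float, init: _initial.InitialValue):
        self.model = model
        self.series = model.series
        self.a = a
        self.b = b
        self.init = init
        self.nobs = len(model.series)

    # -- derived constants -------------------------------------------------
    @property
    def C(self) -> float:
        return self.init.C

    @property
    def b_over_a(self) -> float:
        """Steady-state constant b/a of the whitenized equation (|a| > eps)."""
        if abs(self.a) < A_EPS:
            raise ZeroDivisionError("b/a undefined in the a -> 0 limit")
        return self.b / self.a

    @property
    def regression_resid(self) -> np.ndarray:
        """Residuals of the grey difference equation x0(k) + a z1(k) - b,
        k = 2..n.

        Exactly zero (to round-off) for sequences satisfying the grey
        equation, e.g. geometric series — unlike :attr:`resid`, which
        compares against the restored exponential whose per-step ratio
        e^(-a) only approximates the difference equation's (2-a)/(2+a).
        """
        return self.model.response - self.model.design @ np.array([self.a, self.b])

    @property
    def normal_equation_residual(self) -> float:
        """Max |B^T (Y - B theta)|; ~0 certifies the least-squares solution."""
        theta = np.array([self.a, self.b])
        r = self.model.response - self.model.design @ theta
        return float(np.max(np.abs(self.model.design.T @ r)))

    # -- trajectories ------------------------------------------------------
    def time_response(self, k: np.ndarray | int) -> np.ndarray:
        """Accumulated-scale trajectory x1_hat(k) = (C - b/a)e^(-a(k-1)) + b/a."""
        k = np.asarray(k, dtype=float)
        if abs(self.a) < A_EPS:
            return self.C + self.b * (k - 1.0)
        return (self.C - self.b / self.a) * np.exp(-self.a * (k - 1.0)) + self.b / self.a

    @property
    def fittedvalues(self) -> np.ndarray:
        """Restored fitted values for k = 1..n.

        By reporting convention the first fitted value equals the first
        observation (zero first-year residual); the restored formula's value
        at k = 1 enters only the initial-condition optimizer's objective.
        """
        k = np.arange(2, self.nobs + 1)
        return np.concatenate(
            [[self.series.values[0]], restored_values(self.a, self.b, self.C, k)]
        )

    @property
    def resid(self) -> np.ndarray:
        """Residuals eps(k) = x0(k) - x0_hat(k); zero at k = 1 by convention."""
        return self.series.values - self.fittedvalues

    @property
    def relative_errors(self) -> np.ndarray:
        """|eps(k) / x0(k)|, defined for strictly positive observations."""
        return np.abs(self.resid / self.series.values)

    def forecast(self, horizon: int) -> ForecastResult:
        """Restored forecasts for the ``horizon`` years after the sample."""
        if horizon < 1:
            raise HorizonNonPositive(f"horizon must be >= 1, got {horizon}")
        k = np.arange(self.nobs + 1, self.nobs + horizon + 1)
        years = self.series.start_year + k - 1
        return ForecastResult(
            years=years, values=restored_values(self.a, self.b, self.C, k)
        )

    # -- adequacy ----------------------------------------------------------
    def diagnostics(self, divisor: str = "n_minus_1") -> DiagnosticsReport:
        """Average relative error and grey absolute correlation degree tests."""
        return diagnose(self.series.values, self.fittedvalues, divisor=divisor)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.diagnostics()
        s = self.series
        lines = [
            f"GM(1,1) results: {s.label}" + (f" [{s.units}]" if s.units else ""),
            "=" * 58,
            f"nobs {self.nobs}   years {s.start_year}-{s.start_year + self.nobs - 1}"
            + ("   buffered" if s.buffered else ""),
            f"development coefficient a  {round_display(self.a, 3):>10.3f}",
            f"grey action quantity    b  {round_display(self.b, 3):>10.3f}",
            f"initial condition       C  {round_display(self.C, 3):>10.3f}"
            f"  ({self.init.variant})",
            "-" * 58,
            f"{'year':>6} {'observed':>10} {'fitted':>10} {'residual':>10} {'rel.err':>8}",
        ]
        for yr, obs, fit_, res, rel in zip(
            s.years, s.values, self.fittedvalues, self.resid, self.relative_errors
        ):
            lines.append(
                f"{yr:>6} {obs:>10.2f} {round_display(fit_, 2):>10.2f} "
                f"{round_display(res, 4):>10.4f} {round_display(rel, 4):>8.4f}"
            )
        lines += [
            "-" * 58,
            f"avg relative error  {round_display(d.mean_relative_error, 4):.4f}"
            f"  (grade {d.grade_relative_error})",
            f"grey correlation    {round_display(d.correlation_degree, 4):.4f}"
            f"  (grade {d.grade_correlation})",
        ]
        return "\n".join(lines)

    def to_report(self, horizon: int = 0) -> dict:
        """JSON-serialisable report with full-precision and display fields."""
        d = self.diagnostics()
        rep = {
            "label": self.series.label,
            "units": self.series.units,
            "start_year": int(self.series.start_year),
            "buffered": bool(self.series.buffered),
            "a": self.a,
            "b": self.b,
            "C": self.C,
            "init_variant": self.init.variant,
            "a_display": round_display(self.a, 3),
            "b_display": round_display(self.b, 3),
            "C_display": round_display(self.C, 2),
            "observed": self.series.values.tolist(),
            "fitted": self.fittedvalues.tolist(),
            "fitted_display": round_display(self.fittedvalues, 2).tolist(),
            "residuals": self.resid.tolist(),
            "relative_errors": self.relative_errors.tolist(),
            "diagnostics": {
                "mean_relative_error": d.mean_relative_error,
                "correlation_degree": d.correlation_degree,
                "grade_relative_error": d.grade_relative_error,
                "grade_correlation": d.grade_correlation,
            },
        }
        if horizon > 0:
            fc = self.forecast(horizon)
            rep["forecast_years"] = fc.years.tolist()
            rep["forecasts"] = fc.values.tolist()
            rep["forecasts_display"] = round_display(fc.values, 2).tolist()
        return rep

    def plot(self, horizon: int = 0, ax=None):
        """Plot observed, fitted and (optionally) forecast trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        s = self.series
        ax.plot(s.years, s.values, "o-", label="observed")
        ax.plot(s.years, self.fittedvalues, "s--", label="fitted")
        if horizon > 0:
            fc = self.forecast(horizon)
            ax.plot(fc.years, fc.values, "^:", label="forecast")
        ax.set_xlabel("year")
        ax.set_ylabel(s.units or "value")
        ax.set_title(f"GM(1,1): {s.label}")
        ax.legend()
        return ax
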