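"""Grey sequence algebra.

The GM(1,1) model never works on a raw series directly: it first smooths it
by the first-order accumulated generating operation (1-AGO, running partial
sums), regresses on the consecutive-neighbour means of the accumulated
series, and finally restores fitted values by first differencing (the
inverse AGO, or "reduction"). This module holds those primitives plus the
grey strengthening buffer operator used to pre-condition shocked monotone
series before modelling.

All transforms are exact linear maps; ``restore(ago(x)) == x`` to round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .exceptions import NonNegativityViolation, TooShort

__all__ = [
    "AnnualSeries",
    "AccumulatedSeries",
    "MeanSequence",
    "validate",
    "ago",
    "mean_generation",
    "restore",
    "strengthen_buffer",
    "round_display",
]

#: Minimum usable length: the grey regression runs over k = 2..n, so n >= 4
#: leaves at least three rows to estimate two parameters.
MIN_LENGTH = 4


@dataclass(frozen=True)
class AnnualSeries:
    """A labelled, year-indexed sequence of non-negative observations.

    Parameters
    ----------
    label : str
        Short identifier, e.g. ``"W1"``.
    start_year : int
        Calendar year of the first observation. Grey-model index
        ``k = year - start_year + 1`` (k = 1..n).
    values : array-like of float
        Ordered observations, one per consecutive year.
    units : str, optional
        Unit annotation carried through to reports (e.g. ``"10^8 tons"``).
    buffered : bool
        Whether a buffer operator has already been applied.
    """

    label: str
    start_year: int
    values: np.ndarray
    units: str = ""
    buffered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).copy()
        )
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(len(self.values))

    def year_to_index(self, year: int) -> int:
        """Grey-model index k of a calendar year (1-based)."""
        return year - self.start_year + 1


@dataclass(frozen=True)
class AccumulatedSeries:
    """1-AGO partial sums of an :class:`AnnualSeries`."""

    parent: AnnualSeries
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.values
        if vals is None:
            vals = np.cumsum(self.parent.values)
        object.__setattr__(self, "values", np.asarray(vals, dtype=float))
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MeanSequence:
    """Consecutive-neighbour means of an accumulated series, indexed k = 2..n."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.values)


def validate(series: AnnualSeries) -> AnnualSeries:
    """Check GM(1,1) input invariants and return the series unchanged.

    Raises
    ------
    NonNegativityViolation
        If any observation is negative.
    TooShort
        If fewer than 4 observations.

    Warns
    -----
    UserWarning
        If any observation is exactly zero (relative errors are then
        undefined downstream).
    """
    if np.any(series.values < 0):
        bad = series.values[series.values < 0]
        raise NonNegativityViolation(
            f"{series.label}: negative observation(s) {bad.tolist()}; "
            "GM(1,1) requires a non-negative series"
        )
    if len(series) < MIN_LENGTH:
        raise TooShort(
            f"{series.label}: n={len(series)} < {MIN_LENGTH}; too short for GM(1,1)"
        )
    if np.any(series.values == 0):
        warnings.warn(
            f"{series.label}: zero observation(s) present; relative-error "
            "diagnostics will be undefined",
            stacklevel=2,
        )
    return series


def ago(series: AnnualSeries) -> AccumulatedSeries:
    """First-order accumulated generating operation: running partial sums."""
    return AccumulatedSeries(parent=series)


def mean_generation(acc: AccumulatedSeries) -> MeanSequence:
    """Means of consecutive accumulated values, z(k) = (x1(k) + x1(k-1)) / 2."""
    v = acc.values
    if len(v) < 2:
        raise TooShort("mean generation needs at least 2 accumulated values")
    return MeanSequence(values=0.5 * (v[1:] + v[:-1]))


def restore(acc: AccumulatedSeries) -> AnnualSeries:
    """Inverse AGO (first differencing): recover the parent-scale series."""
    v = acc.values
    out = np.empty_like(v)
    out[0] = v[0]
    out[1:] = np.diff(v)
    p = acc.parent
    return AnnualSeries(
        label=p.label, start_year=p.start_year, values=out,
        units=p.units, buffered=p.buffered,
    )


def strengthen_buffer(series: AnnualSeries) -> AnnualSeries:
    """Apply the grey strengthening buffer operator.

    For a monotone series x the buffered series is

        x(k)d = (x(1) + ... + x(k-1) + k * x(k)) / (2k - 1),   k = 1..n-1
        x(n)d = x(n)

    which amplifies the underlying trend while leaving the newest
    observation untouched. At k = 1 the general formula reduces to x(1).
    The operator is a strengthening operator only for monotone input; on
    non-monotone input it still computes but a warning is emitted.
    """
    x = series.values
    d = np.diff(x)
    if not (np.all(d >= 0) or np.all(d <= 0)):
        warnings.warn(
            f"{series.label}: series is not monotone; the strengthening "
            "buffer operator is only meaningful for monotone sequences",
            stacklevel=2,
        )
    n = len(x)
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)[:-1]])  # prefix sums x(1..k-1)
    k = np.arange(1, n + 1)
    out = (csum + k * x) / (2 * k - 1)
    out[-1] = x[-1]
    return replace(series, values=out, buffered=True)


def round_display(values: np.ndarray | float, decimals: int = 2) -> np.ndarray | float:
    """Round half away from zero for report display.

    numpy's banker's rounding would turn 2.305 into 2.30; published tables
    round half up. Goes through ``decimal`` on the shortest repr so that
    e.g. 2.305 (stored as 2.30499...96) still rounds to 2.31.
    """
    quantum = Decimal(1).scaleb(-decimals)

    def _one(v: float) -> float:
        # pre-round far below display precision so accumulated float noise
        # (19.065 stored as 19.0649...98) does not flip the half-up tie
        return float(
            Decimal(repr(round(float(v), 12))).quantize(quantum, rounding=ROUND_HALF_UP)
        )

    v = np.asarray(values, dtype=float)
    if v.ndim == 0:
        return _one(float(v))
    return np.array([_one(x) for x in v.ravel()]).reshape(v.shape)
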