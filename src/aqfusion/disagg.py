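"""Temporal disaggregation of monthly and biannual series to daily resolution.

Monthly emission values (anchored at mid-month) and biannual livestock
censuses (anchored at 30 June / 31 December, with an optional pre-period
31 December start value) are raised to daily resolution with the
shape-preserving piecewise cubic Hermite interpolant (PCHIP, Fritsch-Carlson
derivative limiting).  PCHIP passes through every knot, preserves local
monotonicity and never leaves the knot range on an interval, so positive
knots yield positive daily values — the reason it is preferred over classic
cubic splines for counts and fluxes.  Nominal (categorical or annual) data
expand to daily piecewise-constant series instead.

No extrapolation is performed: days beyond the knot span stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "KnotSeries",
    "PchipDisaggregator",
    "pchip_daily",
    "monthly_knots",
    "biannual_knots",
    "piecewise_constant_daily",
]


@dataclass
class KnotSeries:
    """Values anchored at strictly increasing calendar dates."""

    knot_dates: pd.DatetimeIndex
    knot_values: np.ndarray

    def __post_init__(self) -> None:
        self.knot_dates = pd.DatetimeIndex(self.knot_dates)
        self.knot_values = np.asarray(self.knot_values, dtype=float)
        if len(self.knot_dates) < 2:
            raise ValueError("need at least 2 knots")
        if len(self.knot_dates) != len(self.knot_values):
            raise ValueError("knot dates and values must align")
        if not self.knot_dates.is_monotonic_increasing or self.knot_dates.has_duplicates:
            raise ValueError("knot dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.knot_dates)


def _to_days(dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar dates as float days since the Unix epoch."""
    return pd.DatetimeIndex(dates).asi8 / 86_400_000_000_000.0


class PchipDisaggregator:
    """Shape-preserving daily interpolator over a knot series.

    Estimator-style interface: :meth:`fit` builds the Fritsch-Carlson
    Hermite interpolant through the knots; :meth:`transform` evaluates it on
    a daily date grid, refusing dates outside the knot span.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "PchipDisaggregator":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, knots: KnotSeries) -> "PchipDisaggregator":
        self.knots_ = knots
        # scipy's derivative limiter divides by zero secant slopes before
        # masking them; harmless, so keep it quiet
        with np.errstate(divide="ignore", invalid="ignore"):
            self.interpolant_ = PchipInterpolator(
                _to_days(knots.knot_dates), knots.knot_values, extrapolate=False
            )
        return self

    def transform(self, dates) -> pd.Series:
        if not hasattr(self, "interpolant_"):
            raise RuntimeError("PchipDisaggregator must be fitted before transform")
        idx = pd.DatetimeIndex(dates)
        x = _to_days(idx)
        lo, hi = _to_days(self.knots_.knot_dates)[[0, -1]]
        if len(x) and (x.min() < lo or x.max() > hi):
            raise ValueError("dates outside the knot span; extrapolation refused")
        return pd.Series(self.interpolant_(x), index=idx)

    def fit_transform(self, knots: KnotSeries, dates) -> pd.Series:
        return self.fit(knots).transform(dates)


def pchip_daily(knots: KnotSeries, dates) -> pd.Series:
    """Evaluate the shape-preserving interpolant through ``knots`` at ``dates``.

    Thin wrapper over :class:`PchipDisaggregator`.
    """
    return PchipDisaggregator().fit_transform(knots, dates)


def monthly_knots(values, start_month: str | pd.Period | None = None) -> KnotSeries:
    """Anchor one value per month at the 15th of that month.

    ``values`` is either a sequence (with ``start_month`` like ``"2016-01"``)
    or a pandas Series indexed by month starts / PeriodIndex.  Months must be
    consecutive; interior gaps are rejected.
    """
    if isinstance(values, pd.Series):
        idx = values.index
        if isinstance(idx, pd.PeriodIndex):
            periods = idx
        else:
            periods = pd.DatetimeIndex(idx).to_period("M")
        vals = values.to_numpy(dtype=float)
    else:
        if start_month is None:
            raise ValueError("start_month required for a bare value sequence")
        start = pd.Period(start_month, freq="M")
        periods = pd.period_range(start, periods=len(values), freq="M")
        vals = np.asarray(values, dtype=float)
    if len(periods) < 2:
        raise ValueError("need at least 2 monthly values")
    steps = np.diff(periods.asi8)
    if np.any(steps != 1):
        raise ValueError("months must be consecutive with no interior gaps")
    dates = pd.DatetimeIndex(
        [p.to_timestamp() + pd.Timedelta(days=14) for p in periods]
    )
    return KnotSeries(knot_dates=dates, knot_values=vals)


def _is_census_date(d: pd.Timestamp) -> bool:
    return (d.month, d.day) in {(6, 30), (12, 31)}


def biannual_knots(census: pd.Series, start_value: float | None = None,
                   start_date=None) -> KnotSeries:
    """Knots for a biannual (30 June / 31 December) census series.

    ``census`` is indexed by census dates, each a 30 June or a 31 December.
    When a pre-period ``start_value`` is supplied it is prepended at
    ``start_date`` (default: the 31 December preceding the first census) to
    reduce edge effects; otherwise the daily series simply starts at the
    first census knot.  Out-of-order input is rejected, not sorted.
    """
    dates = pd.DatetimeIndex(census.index)
    if len(dates) == 0:
        raise ValueError("need at least one census value")
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValueError("census dates must be strictly increasing")
    for d in dates:
        if not _is_census_date(d):
            raise ValueError(f"{d.date()} is not a 30 June / 31 December census date")
    values = census.to_numpy(dtype=float)
    if start_value is not None:
        if start_date is None:
            first = dates[0]
            start_date = pd.Timestamp(year=first.year - 1, month=12, day=31)
        start_date = pd.Timestamp(start_date)
        if start_date >= dates[0]:
            raise ValueError("start_date must precede the first census date")
        dates = pd.DatetimeIndex([start_date]).append(dates)
        values = np.concatenate([[float(start_value)], values])
    return KnotSeries(knot_dates=dates, knot_values=values)


def piecewise_constant_daily(values, dates) -> pd.Series:
    """Expand annual (or single) nominal values to a daily step series.

    ``values`` is a scalar (broadcast to every day), or a mapping/Series
    keyed by year.  Each day carries its year's value; days in years after
    the last available year carry the missing marker (None).  Years must be
    consecutive when more than one is given.
    """
    idx = pd.DatetimeIndex(dates)
    if isinstance(values, (pd.Series, dict)):
        mapping = dict(values)
        if not mapping:
            raise ValueError("empty value mapping")
        years = sorted(int(y) for y in mapping)
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive")
        out = [mapping.get(int(y), None) for y in idx.year]
        return pd.Series(out, index=idx, dtype=object)
    if values is None:
        raise ValueError("empty value list")
    return pd.Series([values] * len(idx), index=idx, dtype=object)
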