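"""Daily aggregation of sub-daily series with the 6-hour gap rule and
propagation of imputation uncertainty to daily means.

Sub-daily (1 h / 2 h) series — possibly imputed — are collapsed onto UTC
calendar days with a per-variable aggregation function (mean, max, min, sum
or mode).  A day is set to missing when it overlaps a consecutive run of
originally-missing entries spanning more than six hours; the regular 2 h
spacing of bi-hourly series is not itself a gap.  For imputed series the
smoother variances of the day's imputed entries are propagated to the daily
mean as

    sigma_d = sqrt( (1/m^2) * sum over imputed t in d of Var(x_t | y) )

with m the number of entries per day (24 for hourly, 12 for bi-hourly), so a
fully observed day has exactly zero uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gapfill import ImputedSeries, RegularSeries

__all__ = [
    "AGGREGATION_FUNCTIONS",
    "AggregationSpec",
    "DailySeries",
    "daily_mode",
    "gap_rule_mask",
    "aggregate_daily",
    "propagate_uncertainty",
]

#: Hours above which a consecutive missing run invalidates the day.
GAP_RULE_HOURS = 6.0

AGGREGATION_FUNCTIONS = ("mean", "max", "min", "sum", "mode")


@dataclass(frozen=True)
class AggregationSpec:
    """Daily aggregation function and output label for one variable."""

    function: str
    variable_name: str = ""

    def __post_init__(self) -> None:
        if self.function not in AGGREGATION_FUNCTIONS:
            raise ValueError(
                f"unknown aggregation function {self.function!r}; "
                f"expected one of {AGGREGATION_FUNCTIONS}"
            )


@dataclass
class DailySeries:
    """Calendar-day aggregates with per-day imputation uncertainty."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    sigma_d: np.ndarray
    n_imputed: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values)
        self.sigma_d = np.asarray(self.sigma_d, dtype=float)
        self.n_imputed = np.asarray(self.n_imputed, dtype=int)
        n = len(self.dates)
        if not (len(self.values) == len(self.sigma_d) == len(self.n_imputed) == n):
            raise ValueError("all per-day arrays must share the date length")
        finite = ~np.isnan(self.sigma_d)
        if np.any(self.sigma_d[finite] < 0):
            raise ValueError("sigma_d must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "sigma_d": self.sigma_d,
             "n_imputed": self.n_imputed},
            index=self.dates,
        )


def daily_mode(values) -> object:
    """Most frequent category; ties break to the earliest occurrence."""
    seq = list(values)
    if not seq:
        raise ValueError("empty day")
    counts: dict = {}
    for item in seq:
        counts[item] = counts.get(item, 0) + 1
    best = max(counts.values())
    for item in seq:  # first occurrence order settles ties
        if counts[item] == best:
            return item
    raise AssertionError("unreachable")


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    runs = []
    n = len(missing)
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def gap_rule_mask(series: RegularSeries | ImputedSeries) -> pd.Series:
    """Boolean per-day mask: True where the day fails the 6-hour gap rule.

    Runs of originally-missing entries are measured on the full series (a gap
    crossing midnight counts against every day it touches); a run spanning
    strictly more than six hours invalidates the day.
    """
    base = series.base if isinstance(series, ImputedSeries) else series
    missing = base.missing_mask
    stamps = base.timestamps
    days = stamps.floor("D")
    bad = np.zeros(len(missing), dtype=bool)
    step_h = base.step_hours
    for start, stop in _missing_runs(missing):
        if (stop - start) * step_h > GAP_RULE_HOURS:
            bad[start:stop] = True
    out = pd.Series(bad, index=days).groupby(level=0).any()
    out.index = pd.DatetimeIndex(out.index)
    return out


def aggregate_daily(
    series: RegularSeries | ImputedSeries,
    spec: AggregationSpec,
    skip_missing: bool = False,
) -> DailySeries:
    """Collapse a regular (possibly imputed) series to UTC calendar days.

    Imputed series aggregate their filled values, so numeric functions see a
    complete day; unimputed series propagate remaining NaNs unless
    ``skip_missing`` asks for available-case aggregation.  Days failing the
    gap rule are set missing regardless of imputation, as is their sigma_d.
    Partial first/last days are aggregated over the entries present.
    """
    if isinstance(series, ImputedSeries):
        base = series.base
        values = series.filled_values
        variances = np.where(series.imputed_mask, series.smoothed_variance, 0.0)
        n_imp = series.imputed_mask.astype(int)
    else:
        base = series
        values = series.values
        variances = np.zeros(len(base))
        n_imp = np.zeros(len(base), dtype=int)

    days = base.timestamps.floor("D")
    frame = pd.DataFrame(
        {"value": values, "var": variances, "imp": n_imp}, index=days
    )
    grouped = frame.groupby(level=0)

    numeric_funcs = {
        "mean": (np.mean, np.nanmean),
        "max": (np.max, np.nanmax),
        "min": (np.min, np.nanmin),
        "sum": (np.sum, np.nansum),
    }
    if spec.function == "mode":
        agg = grouped["value"].agg(daily_mode)
    else:
        func = numeric_funcs[spec.function][1 if skip_missing else 0]
        agg = grouped["value"].agg(lambda s: func(s.to_numpy()))

    m = int(round(24.0 / base.step_hours))
    sigma = np.sqrt(grouped["var"].sum()) / m
    n_imputed = grouped["imp"].sum()

    bad = gap_rule_mask(series).reindex(agg.index, fill_value=False)
    out_values = agg.to_numpy(dtype=object if spec.function == "mode" else float)
    sigma = sigma.to_numpy(dtype=float)
    if spec.function == "mode":
        out_values[bad.to_numpy()] = None
    else:
        out_values[bad.to_numpy()] = np.nan
        sigma[np.isnan(out_values.astype(float))] = np.nan
    sigma[bad.to_numpy()] = np.nan
    return DailySeries(
        dates=pd.DatetimeIndex(agg.index),
        values=out_values,
        sigma_d=sigma,
        n_imputed=n_imputed.to_numpy(),
    )


def propagate_uncertainty(series: ImputedSeries) -> pd.Series:
    """Per-day imputation standard deviation of the daily mean.

    Only imputed entries contribute; the divisor is the squared count of
    entries per day at the series' step.  Days failing the gap rule get NaN.
    """
    base = series.base
    m = int(round(24.0 / base.step_hours))
    days = base.timestamps.floor("D")
    var = np.where(series.imputed_mask, series.smoothed_variance, 0.0)
    sigma = pd.Series(var, index=days).groupby(level=0).sum().pow(0.5) / m
    sigma.index = pd.DatetimeIndex(sigma.index)
    bad = gap_rule_mask(series).reindex(sigma.index, fill_value=False)
    sigma[bad] = np.nan
    sigma.name = "sigma_d"
    return sigma
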