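"""Per-sensor gap imputation for hourly / bi-hourly / daily concentration series.

A pollutant series is first regularised: its sampling step is detected as the
mode of the inter-timestamp gaps, values are placed on the implied regular
grid, and non-validated or negative readings become missing.  Missing entries
are then imputed with a scalar state-space model

    x_t = A x_{t-1} + B u_t          (latent "true" concentration)
    y_t = x_t + eps_t                (observation)

with u_t, eps_t independent unit-variance Gaussian white noises.  A and B are
estimated per series by maximising the Gaussian prediction-error likelihood
(optimisation started at A = B = 1), and the Kalman smoother supplies the
conditional mean and variance of every latent state given the whole observed
series — the mean fills the gap, the variance quantifies the imputation
uncertainty that is later propagated to daily averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "SUPPORTED_STEPS",
    "RegularSeries",
    "SSMParams",
    "ImputedSeries",
    "detect_resolution",
    "clean",
    "fit_ssm",
    "kalman_smooth",
    "KalmanImputer",
    "read_sensor_csv",
    "write_imputed_csv",
]

#: Sampling steps the pipeline supports.
SUPPORTED_STEPS = (pd.Timedelta("1h"), pd.Timedelta("2h"), pd.Timedelta("24h"))


@dataclass
class RegularSeries:
    """Equally spaced concentration series with NaN as the missing marker.

    Timestamps are implied by ``(start, step, len(values))``; values are in
    ug/m3 and non-negative wherever observed (cleaning enforces this).
    """

    start: pd.Timestamp
    step: pd.Timedelta
    values: np.ndarray
    station_id: str = ""
    pollutant: str = ""

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.step = pd.Timedelta(self.step)
        if self.step not in SUPPORTED_STEPS:
            raise ValueError(f"unsupported sampling step {self.step}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq=self.step)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def step_hours(self) -> float:
        return self.step / pd.Timedelta("1h")


@dataclass
class SSMParams:
    """Maximum-likelihood parameters of the scalar state-space model."""

    A: float
    B: float
    measurement_sd: float = 1.0
    loglik: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    message: str = ""


@dataclass
class ImputedSeries:
    """A :class:`RegularSeries` with gaps filled by the Kalman smoother.

    ``filled_values`` keeps observed values untouched and substitutes the
    smoothed state mean at missing entries; ``smoothed_variance`` is
    Var(x_t | y_1..y_n) at every entry.
    """

    base: RegularSeries
    filled_values: np.ndarray
    imputed_mask: np.ndarray
    smoothed_variance: np.ndarray
    params: SSMParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.base)
        for name in ("filled_values", "imputed_mask", "smoothed_variance"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        self.filled_values = np.asarray(self.filled_values, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        self.smoothed_variance = np.asarray(self.smoothed_variance, dtype=float)
        if not np.array_equal(self.imputed_mask, self.base.missing_mask):
            raise ValueError("imputed_mask must flag exactly the missing entries")
        if np.any(self.smoothed_variance < 0):
            raise ValueError("smoothed variances must be non-negative")

    def __len__(self) -> int:
        return len(self.base)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.base.timestamps


def detect_resolution(timestamps) -> pd.Timedelta:
    """Detect the sampling step as the modal gap between successive timestamps.

    The modal gap must be one of 1 h, 2 h or 24 h; a tie between two equally
    frequent gaps resolves to the smaller (finer) one.

    Parameters
    ----------
    timestamps : sequence of datetimes, strictly increasing, length >= 3.
    """
    ts = pd.DatetimeIndex(timestamps)
    if len(ts) < 3:
        raise ValueError("need at least 3 timestamps to detect a resolution")
    gaps = np.diff(ts.asi8)
    if np.any(gaps <= 0):
        raise ValueError("timestamps must be strictly increasing")
    uniq, counts = np.unique(gaps, return_counts=True)
    # np.unique sorts ascending, so argmax on counts already prefers the
    # smaller gap on ties.
    modal = pd.Timedelta(int(uniq[np.argmax(counts)]), unit="ns")
    if modal not in SUPPORTED_STEPS:
        raise ValueError(f"modal gap {modal} outside supported set {SUPPORTED_STEPS}")
    return modal


def clean(
    frame: pd.DataFrame,
    step: pd.Timedelta | str | None = None,
    station_id: str = "",
    pollutant: str = "",
) -> RegularSeries:
    """Regularise a raw sensor series onto its step grid and drop invalid values.

    ``frame`` has columns ``timestamp``, ``value`` and optionally ``validated``
    (0/1; absent means all validated).  Values flagged not-validated and
    negative values become missing, as do grid slots with no reading.
    Timestamps that do not fall on the grid implied by the first timestamp and
    the step are discarded (their slots stay missing).

    Raises on duplicate timestamps mapping to the same grid slot.
    """
    if frame.empty:
        raise ValueError("empty input series")
    ts = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
    if ts.tz is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    order = np.argsort(ts.asi8, kind="stable")
    ts = ts[order]
    vals = np.asarray(frame["value"], dtype=float)[order]
    if "validated" in frame.columns:
        valid = np.asarray(frame["validated"])[order].astype(bool)
    else:
        valid = np.ones(len(vals), dtype=bool)

    if step is None:
        step = detect_resolution(ts)
    step = pd.Timedelta(step)
    if step not in SUPPORTED_STEPS:
        raise ValueError(f"unsupported sampling step {step}")

    step_ns = step.value
    offsets = ts.asi8 - ts.asi8[0]
    on_grid = offsets % step_ns == 0
    slots = offsets[on_grid] // step_ns
    if len(np.unique(slots)) != len(slots):
        raise ValueError("duplicate timestamps on the regular grid")

    n = int(offsets[-1] // step_ns) + 1
    values = np.full(n, np.nan)
    v = vals[on_grid].copy()
    ok = valid[on_grid] & (v >= 0)
    v[~ok] = np.nan
    values[slots] = v
    return RegularSeries(
        start=ts[0], step=step, values=values,
        station_id=station_id, pollutant=pollutant,
    )


# ---------------------------------------------------------------------------
# Kalman filter / smoother for the scalar AR(1)-plus-noise model
# ---------------------------------------------------------------------------

def _initial_conditions(values: np.ndarray) -> tuple[float, float]:
    """Prior mean/variance for x_1: first observation, 10 x sample variance.

    A wide data-driven prior stands in for a formal diffuse initialisation;
    degenerate series (fewer than two observations or zero spread) fall back
    to a variance of 10.
    """
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValueError("series has no observed values")
    mu0 = float(obs[0])
    if obs.size >= 2:
        s2 = float(np.var(obs, ddof=1))
    else:
        s2 = 0.0
    p0 = 10.0 * s2 if s2 > 0 else 10.0
    return mu0, p0


_LOG_2PI = math.log(2.0 * math.pi)


def _loglik(y: list[float], a: float, b: float, r: float,
            mu0: float, p0: float) -> float:
    """Gaussian prediction-error log-likelihood; missing entries are skipped.

    Pure-Python scalar recursion: for series of a few thousand points this is
    faster than a numpy loop and is called hundreds of times per fit.
    """
    q = b * b
    x, p = mu0, p0
    first = True
    ll = 0.0
    for obs in y:
        if first:
            first = False
        else:
            x = a * x
            p = a * a * p + q
        if obs == obs:  # not NaN
            s = p + r
            e = obs - x
            ll -= 0.5 * (_LOG_2PI + math.log(s) + e * e / s)
            k = p / s
            x = x + k * e
            p = (1.0 - k) * p
    return ll


def _filter_smooth(values: np.ndarray, a: float, b: float, r: float,
                   mu0: float, p0: float) -> tuple[np.ndarray, np.ndarray]:
    """Kalman filter then Rauch-Tung-Striebel smoother.

    Returns smoothed state means and variances Var(x_t | y_1..y_n).
    Missing observations trigger a prediction-only step.
    """
    n = len(values)
    q = b * b
    xp = np.empty(n)  # one-step-ahead predicted mean
    pp = np.empty(n)  # predicted variance
    xf = np.empty(n)  # filtered mean
    pf = np.empty(n)  # filtered variance
    x, p = mu0, p0
    for t in range(n):
        if t > 0:
            x = a * x
            p = a * a * p + q
        xp[t], pp[t] = x, p
        obs = values[t]
        if obs == obs:
            s = p + r
            k = p / s
            x = x + k * (obs - x)
            p = (1.0 - k) * p
        xf[t], pf[t] = x, p

    xs = np.empty(n)
    ps = np.empty(n)
    xs[-1], ps[-1] = xf[-1], pf[-1]
    for t in range(n - 2, -1, -1):
        if pp[t + 1] > 0:
            j = pf[t] * a / pp[t + 1]
        else:
            j = 0.0
        xs[t] = xf[t] + j * (xs[t + 1] - xp[t + 1])
        ps[t] = pf[t] + j * j * (ps[t + 1] - pp[t + 1])
    return xs, ps


class KalmanImputer:
    """Maximum-likelihood state-space imputer for a single regular series.

    Estimator-style interface: :meth:`fit` maximises the prediction-error
    likelihood of the AR(1)-plus-noise model over ``(A, log B)`` starting from
    ``(1, log 1)`` with a derivative-free simplex search; :meth:`transform`
    runs the Kalman smoother with the fitted parameters and returns an
    :class:`ImputedSeries`.

    Parameters
    ----------
    measurement_sd : float, default 1.0
        Observation noise standard deviation, fixed (not estimated).  The
        model is stated on the raw concentration scale with unit measurement
        variance.
    prescale : bool, default False
        If True, divide the series by the sample SD of its observed values
        before fitting and undo the scaling on the smoothed output.  Escape
        hatch for poorly scaled series; off by default for fidelity to the
        raw-scale model.
    a_start, b_start : float, default 1.0
        Optimiser start point.
    tol : float, default 1e-6
        Convergence tolerance on the objective.
    min_observations : int, default 10
        Minimum number of non-missing values required to fit.

    Attributes
    ----------
    A_, B_ : float
        Fitted transition and innovation-scale parameters.
    loglik_ : float
        Maximised log-likelihood (on the working scale).
    converged_ : bool
    params_ : SSMParams
    """

    def __init__(self, measurement_sd: float = 1.0, prescale: bool = False,
                 a_start: float = 1.0, b_start: float = 1.0,
                 tol: float = 1e-6, min_observations: int = 10):
        self.measurement_sd = measurement_sd
        self.prescale = prescale
        self.a_start = a_start
        self.b_start = b_start
        self.tol = tol
        self.min_observations = min_observations

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "measurement_sd": self.measurement_sd,
            "prescale": self.prescale,
            "a_start": self.a_start,
            "b_start": self.b_start,
            "tol": self.tol,
            "min_observations": self.min_observations,
        }

    def set_params(self, **params) -> "KalmanImputer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -----------------------------------------------------------------------
    def _working_values(self, series: RegularSeries) -> tuple[np.ndarray, float]:
        scale = 1.0
        values = series.values
        if self.prescale:
            obs = values[~np.isnan(values)]
            sd = float(np.std(obs, ddof=1)) if obs.size >= 2 else 0.0
            if sd > 0:
                scale = sd
        return values / scale, scale

    def fit(self, series: RegularSeries) -> "KalmanImputer":
        n_obs = int((~series.missing_mask).sum())
        if n_obs < self.min_observations:
            raise ValueError(
                f"need >= {self.min_observations} observed values, got {n_obs}"
            )
        values, _ = self._working_values(series)
        mu0, p0 = _initial_conditions(values)
        y = [float(v) for v in values]
        r = self.measurement_sd ** 2

        def nll(theta):
            a, logb = theta
            return -_loglik(y, a, math.exp(logb), r, mu0, p0)

        res = minimize(
            nll,
            x0=np.array([self.a_start, math.log(self.b_start)]),
            method="Nelder-Mead",
            options={"fatol": self.tol, "xatol": 1e-6, "maxiter": 2000},
        )
        self.A_ = float(res.x[0])
        self.B_ = float(math.exp(res.x[1]))
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success) and math.isfinite(res.fun)
        self.params_ = SSMParams(
            A=self.A_, B=self.B_, measurement_sd=self.measurement_sd,
            loglik=self.loglik_, converged=self.converged_,
            n_iter=int(res.nit), message=str(res.message),
        )
        return self

    def transform(self, series: RegularSeries) -> ImputedSeries:
        if not hasattr(self, "params_"):
            raise RuntimeError("KalmanImputer must be fitted before transform")
        return kalman_smooth(series, self.params_, prescale=self.prescale)

    def fit_transform(self, series: RegularSeries) -> ImputedSeries:
        return self.fit(series).transform(series)


def fit_ssm(series: RegularSeries, **kwargs) -> SSMParams:
    """Fit the scalar state-space model by maximum likelihood.

    Thin wrapper over :class:`KalmanImputer`; see there for keyword options.
    """
    return KalmanImputer(**kwargs).fit(series).params_


def kalman_smooth(series: RegularSeries, params: SSMParams,
                  prescale: bool = False) -> ImputedSeries:
    """Impute missing entries of ``series`` with the Kalman smoother.

    Observed entries keep the observation; missing entries take the smoothed
    state mean.  ``smoothed_variance`` holds Var(x_t | all observations) for
    every entry.
    """
    if not (math.isfinite(params.A) and math.isfinite(params.B)):
        raise ValueError("SSM parameters must be finite")
    values = series.values
    scale = 1.0
    if prescale:
        obs = values[~np.isnan(values)]
        sd = float(np.std(obs, ddof=1)) if obs.size >= 2 else 0.0
        if sd > 0:
            scale = sd
    work = values / scale
    mu0, p0 = _initial_conditions(work)
    xs, ps = _filter_smooth(
        work, params.A, params.B, params.measurement_sd ** 2, mu0, p0
    )
    missing = np.isnan(values)
    filled = np.where(missing, xs * scale, values)
    return ImputedSeries(
        base=series,
        filled_values=filled,
        imputed_mask=missing,
        smoothed_variance=ps * scale * scale,
        params=params,
    )


# ---------------------------------------------------------------------------
# I/O dialects
# ---------------------------------------------------------------------------

def read_sensor_csv(path) -> pd.DataFrame:
    """Read a long-format sensor CSV.

    Columns: ``station_id, pollutant, timestamp`` (ISO-8601 UTC), ``value``,
    ``validated`` (0/1).
    """
    frame = pd.read_csv(path)
    required = {"station_id", "pollutant", "timestamp", "value", "validated"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sensor CSV missing columns: {sorted(missing)}")
    stamps = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"], utc=True))
    frame["timestamp"] = stamps.tz_localize(None) if stamps.tz is None \
        else stamps.tz_convert("UTC").tz_localize(None)
    return frame


def write_imputed_csv(imputed: ImputedSeries, path) -> None:
    """Write per-entry imputation diagnostics (filled value, mask, variance)."""
    frame = pd.DataFrame(
        {
            "station_id": imputed.base.station_id,
            "pollutant": imputed.base.pollutant,
            "timestamp": imputed.timestamps.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "filled_value": imputed.filled_values,
            "imputed": imputed.imputed_mask.astype(int),
            "smoothed_variance": imputed.smoothed_variance,
        }
    )
    frame.to_csv(path, index=False, na_rep="NaN")
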