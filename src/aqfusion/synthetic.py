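"""Seeded generators for every input class the harmonisation pipeline consumes.

The generators emulate the statistical structure the pipeline's methods
assume — an irregular station network over a lat/lon box, hourly/bi-hourly
pollutant series driven by a latent AR(1) state plus a sinusoidal diurnal
cycle and unit-variance observation noise, smooth gridded fields, strictly
positive monthly emission fluxes, and biannual municipal livestock counts —
without attempting to match any real region's spatial covariance or
magnitudes.  Latent truths are retained alongside the observations so tests
can measure true imputation error.  Identical configurations (including the
seed) produce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .spatial import GridField, MunicipalTable

__all__ = [
    "SynthConfig",
    "SyntheticSeries",
    "gen_registry",
    "gen_hourly_series",
    "gen_grid_field",
    "gen_municipal_counts",
    "write_sensor_csv",
    "write_registry_csv",
    "write_municipal_csv",
]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration shared by all synthetic generators.

    Defaults emulate the published study conditions: a 141-station network
    over an extended-Lombardy-sized box, the 2016-2021 period, a 0.25-degree
    grid, a persistent hourly AR(1) state observed with unit-variance noise,
    and a visible diurnal cycle.  Missingness combines independent Bernoulli
    dropout with geometric-length gap bursts so that runs longer than six
    hours occur.
    """

    n_stations: int = 141
    period_start: str = "2016-01-01"
    period_end: str = "2021-12-31"
    #: (lat_min, lat_max, lon_min, lon_max) in degrees.
    grid_extent: tuple[float, float, float, float] = (44.2, 46.9, 8.2, 11.5)
    grid_step: float = 0.25
    ar_coefficient: float = 0.9
    innovation_scale: float = 2.0  # ug/m3
    diurnal_amplitude: float = 5.0  # ug/m3
    baseline_level: float = 20.0  # ug/m3, keeps concentrations mostly positive
    missing_rate: float = 0.10
    gap_burst_mean_length: float = 8.0  # hours; 0 disables bursts
    gap_burst_rate: float = 0.002  # burst starts per time step
    n_municipalities: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be positive")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        lat0, lat1, lon0, lon1 = self.grid_extent
        if lat0 >= lat1 or lon0 >= lon1:
            raise ValueError("grid_extent must be a non-degenerate box")
        if pd.Timestamp(self.period_start) > pd.Timestamp(self.period_end):
            raise ValueError("period_start must not exceed period_end")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, rng_seed=int(seed))

    @property
    def period(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return pd.Timestamp(self.period_start), pd.Timestamp(self.period_end)


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator (stable across runs)."""
    digest = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, digest]))


def _station_type_probabilities() -> tuple[list[tuple[str, str]], np.ndarray]:
    pairs = list(reference.STATION_TYPE_COUNTS)
    counts = np.array([reference.STATION_TYPE_COUNTS[p] for p in pairs], float)
    return pairs, counts / counts.sum()


def gen_registry(cfg: SynthConfig) -> pd.DataFrame:
    """Generate a station registry over the configured box.

    Columns: ``station_id, lat, lon, altitude, municipality, land_use,
    emission_context``.  Station types are drawn from the published
    land-use x emission-context frequencies; municipalities are
    nearest-centroid (Voronoi-like) assignments to a small set of synthetic
    municipality centroids.
    """
    rng = _rng(cfg, "registry")
    lat0, lat1, lon0, lon1 = cfg.grid_extent
    lats = rng.uniform(lat0, lat1, cfg.n_stations)
    lons = rng.uniform(lon0, lon1, cfg.n_stations)
    altitude = np.round(rng.gamma(shape=2.0, scale=120.0, size=cfg.n_stations), 1)
    pairs, probs = _station_type_probabilities()
    drawn = rng.choice(len(pairs), size=cfg.n_stations, p=probs)
    cen_lat, cen_lon = _municipal_centroids(cfg)
    muni_idx = np.argmin(
        np.hypot(lats[:, None] - cen_lat[None, :], lons[:, None] - cen_lon[None, :]),
        axis=1,
    )
    return pd.DataFrame(
        {
            "station_id": [f"STA.SYN{i:04d}" for i in range(cfg.n_stations)],
            "lat": lats,
            "lon": lons,
            "altitude": altitude,
            "municipality": [f"MUN{j:03d}" for j in muni_idx],
            "land_use": [pairs[k][0] for k in drawn],
            "emission_context": [pairs[k][1] for k in drawn],
        }
    )


def _municipal_centroids(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(cfg, "municipalities")
    lat0, lat1, lon0, lon1 = cfg.grid_extent
    return (rng.uniform(lat0, lat1, cfg.n_municipalities),
            rng.uniform(lon0, lon1, cfg.n_municipalities))


@dataclass
class SyntheticSeries:
    """An observed (irregular) series plus its complete latent truth.

    ``observations`` is the long-format sensor table (rows deleted where the
    missingness process struck); ``truth`` and ``latent`` align with
    ``grid_timestamps`` and let tests score imputation against the signal the
    smoother targets (latent state + diurnal cycle + baseline).
    """

    observations: pd.DataFrame
    grid_timestamps: pd.DatetimeIndex
    truth: np.ndarray
    latent: np.ndarray
    missing_mask: np.ndarray
    step: pd.Timedelta


def gen_hourly_series(
    cfg: SynthConfig,
    step: str | pd.Timedelta = "1h",
    station_id: str = "STA.SYN0000",
    pollutant: str = "nh3",
    n_periods: int | None = None,
) -> SyntheticSeries:
    """Generate one pollutant series on a regular step grid with missingness.

    The signal is baseline + diurnal sine (24 h period) + latent AR(1) state
    (coefficient ``ar_coefficient``, innovation SD ``innovation_scale``);
    observations add unit-variance Gaussian noise.  Entries are deleted by an
    independent Bernoulli(``missing_rate``) process plus geometric-length gap
    bursts (mean length ``gap_burst_mean_length`` hours; zero disables
    bursts), and the surviving rows form the irregular observation table.
    """
    step = pd.Timedelta(step)
    if step not in (pd.Timedelta("1h"), pd.Timedelta("2h"), pd.Timedelta("24h")):
        raise ValueError(f"unsupported step {step}")
    start, end = cfg.period
    stamps = pd.date_range(start, end + pd.Timedelta("1D") - step, freq=step)
    if n_periods is not None:
        stamps = stamps[:n_periods]
    n = len(stamps)
    rng = _rng(cfg, f"series/{station_id}/{pollutant}/{step}")

    a, b = cfg.ar_coefficient, cfg.innovation_scale
    latent = np.empty(n)
    scale0 = b / np.sqrt(1.0 - a * a) if abs(a) < 1 else b
    latent[0] = rng.normal(0.0, scale0)
    shocks = rng.normal(0.0, b, n)
    for t in range(1, n):
        latent[t] = a * latent[t - 1] + shocks[t]

    hours = stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0
    diurnal = cfg.diurnal_amplitude * np.sin(2.0 * np.pi * hours / 24.0)
    truth = cfg.baseline_level + diurnal + latent
    observed = truth + rng.normal(0.0, 1.0, n)

    missing = rng.uniform(size=n) < cfg.missing_rate
    if cfg.gap_burst_mean_length > 0:
        steps_per_burst = max(cfg.gap_burst_mean_length / (step / pd.Timedelta("1h")), 1.0)
        starts = np.flatnonzero(rng.uniform(size=n) < cfg.gap_burst_rate)
        lengths = rng.geometric(1.0 / steps_per_burst, size=len(starts))
        for s, length in zip(starts, lengths):
            missing[s: s + int(length)] = True

    obs = pd.DataFrame(
        {
            "station_id": station_id,
            "pollutant": pollutant,
            "timestamp": stamps[~missing],
            "value": observed[~missing],
            "validated": 1,
        }
    )
    return SyntheticSeries(
        observations=obs.reset_index(drop=True),
        grid_timestamps=stamps,
        truth=truth,
        latent=latent,
        missing_mask=missing,
        step=step,
    )


def gen_grid_field(cfg: SynthConfig, cadence: str = "hourly",
                   name: str = "", n_times: int | None = None) -> GridField:
    """Generate a smooth random field on the configured cell-centre grid.

    ``cadence`` is ``"hourly"`` (diurnal temporal cycle) or ``"monthly"``
    (annual cycle, strictly positive values — suitable for emission fluxes).
    The surface is a band-limited sum of low-frequency sinusoids, so nearby
    cells are strongly correlated, as for reanalysis output.
    """
    if cadence not in ("hourly", "monthly"):
        raise ValueError(f"unknown cadence {cadence!r}")
    lat0, lat1, lon0, lon1 = cfg.grid_extent
    lat_axis = np.arange(lat0 + cfg.grid_step / 2, lat1, cfg.grid_step)
    lon_axis = np.arange(lon0 + cfg.grid_step / 2, lon1, cfg.grid_step)
    if len(lat_axis) == 0 or len(lon_axis) == 0:
        raise ValueError("grid extent too small for the grid step: empty grid")
    start, end = cfg.period
    if cadence == "hourly":
        times = pd.date_range(start, end + pd.Timedelta("23h"), freq="1h")
    else:
        times = pd.date_range(start, end, freq="MS") + pd.Timedelta(days=14)
    if n_times is not None:
        times = times[:n_times]

    rng = _rng(cfg, f"grid/{cadence}/{name}")
    la, lo = np.meshgrid(lat_axis, lon_axis, indexing="ij")
    surface = np.zeros_like(la)
    for _ in range(4):  # band-limited random surface
        k_lat, k_lon = rng.uniform(0.2, 1.5, 2)
        phase = rng.uniform(0, 2 * np.pi, 2)
        amp = rng.uniform(0.5, 1.0)
        surface += amp * np.sin(2 * np.pi * k_lat * la / (lat1 - lat0) + phase[0]) \
                       * np.sin(2 * np.pi * k_lon * lo / (lon1 - lon0) + phase[1])

    t_idx = np.arange(len(times), dtype=float)
    if cadence == "hourly":
        cycle = np.sin(2 * np.pi * (times.hour.to_numpy() / 24.0))
        values = 10.0 + 3.0 * cycle[:, None, None] + 2.0 * surface[None, :, :] \
            + 0.3 * rng.normal(size=(len(times), 1, 1))
    else:
        cycle = np.sin(2 * np.pi * t_idx / 12.0)
        # log-space construction keeps monthly fluxes strictly positive
        log_values = -0.5 + 0.4 * cycle[:, None, None] + 0.5 * surface[None, :, :] \
            + 0.1 * rng.normal(size=(len(times), 1, 1))
        values = np.exp(log_values)
    return GridField(lat_axis=lat_axis, lon_axis=lon_axis, times=times,
                     values=values, name=name or cadence)


def gen_municipal_counts(cfg: SynthConfig, species: str = "bovine") -> MunicipalTable:
    """Generate biannual municipal head counts with areas and centroids.

    Counts are produced at 31 December of the year before the period start
    and at every 30 June / 31 December inside the period, following a
    positive multiplicative random walk per municipality (counts are
    non-negative integers; areas are positive km^2).
    """
    rng = _rng(cfg, f"livestock/{species}")
    cen_lat, cen_lon = _municipal_centroids(cfg)
    start, end = cfg.period
    knots = [pd.Timestamp(year=start.year - 1, month=12, day=31)]
    for year in range(start.year, end.year + 1):
        for month, day in ((6, 30), (12, 31)):
            d = pd.Timestamp(year=year, month=month, day=day)
            if start <= d <= end:
                knots.append(d)
    knot_index = pd.DatetimeIndex(knots)

    ids = [f"MUN{j:03d}" for j in range(cfg.n_municipalities)]
    areas = np.round(rng.uniform(5.0, 250.0, cfg.n_municipalities), 2)
    counts: dict[str, pd.Series] = {}
    for j, mid in enumerate(ids):
        level = rng.lognormal(mean=7.0, sigma=1.0)
        walk = np.exp(np.cumsum(rng.normal(0.0, 0.08, len(knot_index))))
        counts[mid] = pd.Series(
            np.round(level * walk).astype(int).clip(min=0),
            index=knot_index, name=species,
        )
    frame = pd.DataFrame(
        {"municipality_id": ids, "lat": cen_lat, "lon": cen_lon, "area_km2": areas}
    )
    return MunicipalTable(frame=frame, counts=counts)


# ---------------------------------------------------------------------------
# Writers emitting the pipeline's input CSV dialects
# ---------------------------------------------------------------------------

def write_sensor_csv(series: SyntheticSeries, path) -> None:
    """Write the observation table in the long-format sensor dialect."""
    obs = series.observations.copy()
    obs["timestamp"] = pd.DatetimeIndex(obs["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    obs.to_csv(path, index=False, na_rep="NaN")


def write_registry_csv(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, index=False, na_rep="NaN")


def write_municipal_csv(table: MunicipalTable, directory,
                        species: str = "bovine") -> None:
    """Write the municipal registry and the long-format count knots."""
    directory = Path(directory)
    table.frame.to_csv(directory / "municipalities.csv", index=False)
    rows = []
    for mid, series in table.counts.items():
        for date, value in series.items():
            rows.append((mid, date.strftime("%Y-%m-%d"), value))
    pd.DataFrame(rows, columns=["municipality_id", "date", "count"]).to_csv(
        directory / f"counts_{species}.csv", index=False
    )
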