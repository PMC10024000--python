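"""Grid-to-station interpolation and station-to-municipality association.

Gridded reanalysis and emission fields are moved onto station coordinates by
inverse-distance-weighted (IDW) interpolation over the four nearest cell
centres with power parameter 1, distances measured as plain Euclidean
distance in degrees (a great-circle option exists but is not the default,
which reproduces the published operator).  Municipal count tables attach to
stations through the declared municipality, falling back to the nearest
municipality centroid when the declared one is absent from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridField",
    "MunicipalTable",
    "IDWInterpolator",
    "idw_to_point",
    "station_to_municipality",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass
class GridField:
    """Cell-centred values on a regular lat/lon grid with a time axis.

    The value is the grid-cell average; the coordinate is the cell centre.
    ``values`` has shape ``(n_times, n_lat, n_lon)``.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    times: pd.DatetimeIndex
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (("lat_axis", self.lat_axis), ("lon_axis", self.lon_axis)):
            if ax.ndim != 1 or len(ax) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        expected = (len(self.times), len(self.lat_axis), len(self.lon_axis))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with axes {expected}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.lat_axis) * len(self.lon_axis)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "") -> "GridField":
        """Build from a flat table with columns time, lat, lon, value."""
        frame = frame.copy()
        frame["time"] = pd.to_datetime(frame["time"])
        lats = np.unique(frame["lat"].to_numpy(dtype=float))
        lons = np.unique(frame["lon"].to_numpy(dtype=float))
        times = pd.DatetimeIndex(np.unique(frame["time"]))
        pivot = frame.set_index(["time", "lat", "lon"])["value"]
        if pivot.index.has_duplicates:
            raise ValueError("duplicate (time, lat, lon) rows in grid table")
        full = pd.MultiIndex.from_product([times, lats, lons],
                                          names=["time", "lat", "lon"])
        if len(pivot) != len(full):
            raise ValueError("grid table does not cover the full time x lat x lon product")
        vals = pivot.reindex(full).to_numpy(dtype=float)
        return cls(lat_axis=lats, lon_axis=lons, times=times,
                   values=vals.reshape(len(times), len(lats), len(lons)),
                   name=name)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "GridField":
        return cls.from_frame(pd.read_csv(path), name=name)

    def to_frame(self) -> pd.DataFrame:
        tt, la, lo = np.meshgrid(
            np.arange(len(self.times)), self.lat_axis, self.lon_axis, indexing="ij"
        )
        return pd.DataFrame(
            {
                "time": self.times[tt.ravel()],
                "lat": la.ravel(),
                "lon": lo.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame["time"] = frame["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        frame.to_csv(path, index=False, na_rep="NaN")

    @classmethod
    def from_xarray(cls, ds, var: str | None = None) -> "GridField":
        """Build from an xarray Dataset/DataArray with CF-style lat/lon/time."""
        import xarray as xr

        if isinstance(ds, xr.Dataset):
            if var is None:
                var = list(ds.data_vars)[0]
            da = ds[var]
        else:
            da = ds
            var = da.name or ""
        rename = {}
        for cand, target in (("latitude", "lat"), ("longitude", "lon")):
            if cand in da.dims:
                rename[cand] = target
        da = da.rename(rename).transpose("time", "lat", "lon")
        return cls(
            lat_axis=da["lat"].to_numpy(),
            lon_axis=da["lon"].to_numpy(),
            times=pd.DatetimeIndex(da["time"].to_numpy()),
            values=da.to_numpy(),
            name=str(var),
        )

    @classmethod
    def from_netcdf(cls, path, var: str | None = None) -> "GridField":
        import xarray as xr

        with xr.open_dataset(path) as ds:
            return cls.from_xarray(ds.load(), var=var)


def _distances(lat: float, lon: float, lats: np.ndarray, lons: np.ndarray,
               metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.hypot(lats - lat, lons - lon)
    if metric == "greatcircle":
        p1, p2 = np.radians(lat), np.radians(lats)
        dlam = np.radians(lons - lon)
        central = np.arccos(
            np.clip(np.sin(p1) * np.sin(p2)
                    + np.cos(p1) * np.cos(p2) * np.cos(dlam), -1.0, 1.0)
        )
        return _EARTH_RADIUS_KM * central
    raise ValueError(f"unknown metric {metric!r}")


class IDWInterpolator:
    """Inverse-distance-weighted grid-to-point interpolator.

    Estimator-style interface: :meth:`fit` stores the flattened cell centres
    of a :class:`GridField`; :meth:`transform` maps an ``(n_points, 2)`` array
    of (lat, lon) pairs to an ``(n_points, n_times)`` array of interpolated
    values.

    For each point the ``n_neighbors`` nearest cell centres are combined with
    weights proportional to ``1/d**power``, normalised to one.  A tie at the
    last neighbour rank resolves to the cell with the smaller (lat, lon)
    lexicographic order; a point exactly on a cell centre returns that cell's
    values (the zero-distance limit of the weights).

    Parameters
    ----------
    n_neighbors : int, default 4
    power : float, default 1.0
    metric : {"euclidean", "greatcircle"}, default "euclidean"
        Euclidean distance in degrees reproduces the published operator.
    """

    def __init__(self, n_neighbors: int = 4, power: float = 1.0,
                 metric: str = "euclidean"):
        self.n_neighbors = n_neighbors
        self.power = power
        self.metric = metric

    def get_params(self, deep: bool = True) -> dict:
        return {"n_neighbors": self.n_neighbors, "power": self.power,
                "metric": self.metric}

    def set_params(self, **params) -> "IDWInterpolator":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, field: GridField) -> "IDWInterpolator":
        if field.n_cells < self.n_neighbors:
            raise ValueError(
                f"grid has {field.n_cells} cells; need >= {self.n_neighbors}"
            )
        la, lo = np.meshgrid(field.lat_axis, field.lon_axis, indexing="ij")
        self.cell_lat_ = la.ravel()
        self.cell_lon_ = lo.ravel()
        self.cell_values_ = field.values.reshape(len(field.times), -1)
        self.times_ = field.times
        return self

    def _point(self, lat: float, lon: float) -> np.ndarray:
        d = _distances(lat, lon, self.cell_lat_, self.cell_lon_, self.metric)
        # order by distance, breaking ties lexicographically on (lat, lon)
        order = np.lexsort((self.cell_lon_, self.cell_lat_, d))
        near = order[: self.n_neighbors]
        dn = d[near]
        if dn[0] == 0.0:
            return self.cell_values_[:, near[0]].copy()
        w = 1.0 / dn ** self.power
        w /= w.sum()
        return self.cell_values_[:, near] @ w

    def transform(self, points) -> np.ndarray:
        if not hasattr(self, "cell_values_"):
            raise RuntimeError("IDWInterpolator must be fitted before transform")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("points must be (n, 2) (lat, lon) pairs")
        return np.vstack([self._point(lat, lon) for lat, lon in pts])

    def fit_transform(self, field: GridField, points) -> np.ndarray:
        return self.fit(field).transform(points)


def idw_to_point(field: GridField, lat: float, lon: float,
                 **kwargs) -> pd.Series:
    """Interpolate ``field`` to one (lat, lon) point; returns a time series.

    Thin wrapper over :class:`IDWInterpolator`; keyword options pass through.
    """
    interp = IDWInterpolator(**kwargs).fit(field)
    return pd.Series(interp.transform([(lat, lon)])[0], index=field.times,
                     name=field.name or "value")


@dataclass
class MunicipalTable:
    """Per-municipality centroids, areas and biannual count series.

    ``counts`` maps municipality_id -> Series indexed by knot dates; the
    ``frame`` holds one row per municipality with columns
    ``municipality_id, lat, lon, area_km2``.
    """

    frame: pd.DataFrame
    counts: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"municipality_id", "lat", "lon", "area_km2"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"municipal table missing columns: {sorted(missing)}")
        if self.frame.empty:
            raise ValueError("empty municipal table")
        if (self.frame["area_km2"] <= 0).any():
            raise ValueError("municipal areas must be positive")
        for mid, series in self.counts.items():
            idx = pd.DatetimeIndex(series.index)
            if not idx.is_monotonic_increasing or idx.has_duplicates:
                raise ValueError(f"knot dates for {mid} must be strictly increasing")

    @property
    def ids(self) -> list[str]:
        return list(self.frame["municipality_id"])


def station_to_municipality(station: pd.Series | dict,
                            table: MunicipalTable) -> str:
    """Municipality a station's count series comes from.

    The declared municipality wins when the table covers it; otherwise the
    municipality with the nearest centroid (Euclidean degrees) is used — the
    fallback for stations whose own municipality lies outside the covered
    domain.  Equidistant centroids resolve to the lexicographically smaller
    id.
    """
    station = dict(station)
    declared = station.get("municipality")
    ids = table.frame["municipality_id"].astype(str)
    if declared is not None and str(declared) in set(ids):
        return str(declared)
    if "lat" not in station or "lon" not in station:
        raise ValueError("station needs a coordinate for the nearest-centroid fallback")
    d = np.hypot(table.frame["lat"].to_numpy(dtype=float) - float(station["lat"]),
                 table.frame["lon"].to_numpy(dtype=float) - float(station["lon"]))
    order = sorted(range(len(d)), key=lambda i: (d[i], str(ids.iloc[i])))
    return str(ids.iloc[order[0]])
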