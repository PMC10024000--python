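"""Assembly of the long harmonised station x day table and dataset writing.

Every daily station-level series is joined onto the full station x day cross
product (one row per station and calendar day, S x T rows in total), with the
literal token ``NaN`` marking missing cells.  The 41-column schema is five
header columns (station code, latitude, longitude, date, altitude) followed
by the AQ, WE, EM, LI and LA variable blocks.  An explicit, user-supplied
anomaly exclusion list — not an automated outlier search — blanks individual
cells.  The writer renders values in scientific notation with four
significant digits, coordinates in fixed point with nine significant digits,
and dates as YYYY-MM-DD, and emits companion metadata files (station
registry, per-day imputation uncertainty, variable dictionary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference

__all__ = [
    "AnomalyExclusion",
    "HarmonisedTable",
    "period_days",
    "build_table",
    "mask_anomalies",
    "format_value",
    "format_coordinate",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class AnomalyExclusion:
    """One cell to blank: (station, date, variable) plus a reason note."""

    station_id: str
    date: str
    variable: str
    reason: str = ""


def period_days(start, end) -> pd.DatetimeIndex:
    """Inclusive daily grid of the study period (leap days included)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("period start after end")
    return pd.date_range(start.normalize(), end.normalize(), freq="D")


@dataclass
class HarmonisedTable:
    """The long station x day table with the 41-column schema.

    ``frame`` holds one row per (station, date); value columns not supplied
    at build time are filled with the missing marker.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.frame.columns) != reference.ALL_COLUMNS:
            raise ValueError("frame does not follow the 41-column schema")
        key = self.frame[["IDStations", "Time"]]
        if key.duplicated().any():
            raise ValueError("(station, date) pairs must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_stations(self) -> int:
        return self.frame["IDStations"].nunique()

    @property
    def n_days(self) -> int:
        return self.frame["Time"].nunique()


def _normalise_daily(daily: pd.DataFrame, variable: str) -> pd.DataFrame:
    required = {"station_id", "date", "value"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily series for {variable} missing columns {sorted(missing)}")
    out = daily[["station_id", "date", "value"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    return out


def build_table(
    registry: pd.DataFrame,
    daily_series: dict[str, pd.DataFrame] | None,
    period: tuple,
) -> HarmonisedTable:
    """Materialise the full station x day cross product and join the series.

    ``registry`` needs columns ``station_id, lat, lon, altitude``;
    ``daily_series`` maps a schema variable name to a long table with columns
    ``station_id, date, value``.  Cells without a series value carry the
    missing marker.  Duplicate station ids and series referencing unknown
    stations or unknown variables are errors.
    """
    if registry["station_id"].duplicated().any():
        raise ValueError("duplicate station ids in registry")
    days = period_days(*period)
    stations = registry["station_id"].astype(str).tolist()

    index = pd.MultiIndex.from_product(
        [stations, days], names=["IDStations", "Time"]
    )
    table = pd.DataFrame(index=index).reset_index()
    meta = registry.set_index("station_id")
    table["Latitude"] = meta["lat"].reindex(table["IDStations"]).to_numpy()
    table["Longitude"] = meta["lon"].reindex(table["IDStations"]).to_numpy()
    table["Altitude"] = meta["altitude"].reindex(table["IDStations"]).to_numpy()

    for col in reference.VALUE_COLUMNS:
        table[col] = np.nan
        if col in reference.CATEGORICAL_COLUMNS:
            table[col] = table[col].astype(object)

    known = set(stations)
    for variable, daily in (daily_series or {}).items():
        if variable not in reference.VALUE_COLUMNS:
            raise ValueError(f"unknown variable {variable!r}")
        norm = _normalise_daily(daily, variable)
        unknown = set(norm["station_id"].astype(str)) - known
        if unknown:
            raise ValueError(
                f"series for {variable} references unknown stations {sorted(unknown)}"
            )
        keyed = norm.set_index(["station_id", "date"])["value"]
        if keyed.index.has_duplicates:
            raise ValueError(f"duplicate (station, date) in series for {variable}")
        aligned = keyed.reindex(
            pd.MultiIndex.from_arrays([table["IDStations"], table["Time"]])
        )
        if variable in reference.CATEGORICAL_COLUMNS:
            table[variable] = aligned.to_numpy(dtype=object)
        else:
            table[variable] = aligned.to_numpy(dtype=float)

    table = table[reference.ALL_COLUMNS]
    return HarmonisedTable(frame=table)


def mask_anomalies(
    table: HarmonisedTable,
    exclusions,
) -> tuple[HarmonisedTable, pd.DataFrame]:
    """Blank the cells named by an explicit exclusion list.

    ``exclusions`` is an iterable of :class:`AnomalyExclusion` (or a
    DataFrame with columns ``station_id, date, variable[, reason]``).
    Returns the masked table and a report with one row per exclusion and an
    ``applied`` flag; an exclusion referencing an absent (station, date) row
    is reported, not fatal, while an unknown column is an error.
    """
    if isinstance(exclusions, pd.DataFrame):
        records = [
            AnomalyExclusion(str(r.station_id), str(r.date), str(r.variable),
                             str(getattr(r, "reason", "")))
            for r in exclusions.itertuples(index=False)
        ]
    else:
        records = list(exclusions)

    frame = table.frame.copy()
    report_rows = []
    for exc in records:
        if exc.variable not in reference.VALUE_COLUMNS:
            raise ValueError(f"exclusion references unknown column {exc.variable!r}")
        hit = (frame["IDStations"] == exc.station_id) & (
            frame["Time"] == pd.Timestamp(exc.date)
        )
        n = int(hit.sum())
        if n:
            frame.loc[hit, exc.variable] = (
                None if exc.variable in reference.CATEGORICAL_COLUMNS else np.nan
            )
        report_rows.append(
            {"station_id": exc.station_id, "date": exc.date,
             "variable": exc.variable, "reason": exc.reason,
             "applied": bool(n)}
        )
    report = pd.DataFrame(
        report_rows,
        columns=["station_id", "date", "variable", "reason", "applied"],
    )
    return HarmonisedTable(frame=frame), report


# ---------------------------------------------------------------------------
# Formatting and file output
# ---------------------------------------------------------------------------

MISSING_TOKEN = "NaN"


def format_value(x) -> str:
    """Scientific notation with four significant digits, NaN token for missing."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return MISSING_TOKEN
    if isinstance(x, str):
        return x
    return f"{float(x):.3e}"


def format_coordinate(x) -> str:
    """Fixed-point with nine significant digits."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return MISSING_TOKEN
    return np.format_float_positional(
        float(x), precision=9, unique=False, fractional=False, trim="k"
    )


def _render(table: HarmonisedTable) -> pd.DataFrame:
    frame = table.frame.copy()
    out = pd.DataFrame(index=frame.index)
    out["IDStations"] = frame["IDStations"].astype(str)
    out["Latitude"] = frame["Latitude"].map(format_coordinate)
    out["Longitude"] = frame["Longitude"].map(format_coordinate)
    out["Time"] = pd.DatetimeIndex(frame["Time"]).strftime("%Y-%m-%d")
    out["Altitude"] = frame["Altitude"].map(format_value)
    for col in reference.VALUE_COLUMNS:
        if col in reference.CATEGORICAL_COLUMNS:
            out[col] = frame[col].map(
                lambda v: MISSING_TOKEN if v is None or (isinstance(v, float)
                                                         and np.isnan(v)) else str(v)
            )
        else:
            out[col] = frame[col].map(format_value)
    return out


def write_dataset(
    table: HarmonisedTable,
    directory,
    registry: pd.DataFrame | None = None,
    uncertainty: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the harmonised dataset and its companion metadata CSVs.

    Files written into ``directory``:

    - ``Harmonised_Dataset.csv`` — the long table, formatted as described in
      the module docstring;
    - ``Metadata_monitoring_network_registry.csv`` — the station registry
      (when supplied);
    - ``Metadata_AQ_imputation_uncertainty.csv`` — per (station, day, AQ
      variable) imputation sigma: zero for fully observed days, the
      propagated value for imputed days, missing where the concentration
      itself is missing (when supplied; long format with columns
      ``station_id, date, variable, sigma_d``);
    - ``Metadata_variables.csv`` — the variable dictionary (name, block,
      kind).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    main = directory / "Harmonised_Dataset.csv"
    _render(table).to_csv(main, index=False)
    paths["dataset"] = main

    if registry is not None:
        reg = directory / "Metadata_monitoring_network_registry.csv"
        registry.to_csv(reg, index=False, na_rep=MISSING_TOKEN)
        paths["registry"] = reg

    if uncertainty is not None:
        unc = directory / "Metadata_AQ_imputation_uncertainty.csv"
        rendered = uncertainty.copy()
        rendered["date"] = pd.DatetimeIndex(
            pd.to_datetime(rendered["date"])
        ).strftime("%Y-%m-%d")
        rendered["sigma_d"] = rendered["sigma_d"].map(format_value)
        rendered.to_csv(unc, index=False)
        paths["uncertainty"] = unc

    blocks = (
        [("header", c) for c in reference.HEADER_COLUMNS]
        + [("AQ", c) for c in reference.AQ_COLUMNS]
        + [("WE", c) for c in reference.WE_COLUMNS]
        + [("EM", c) for c in reference.EM_COLUMNS]
        + [("LI", c) for c in reference.LI_COLUMNS]
        + [("LA", c) for c in reference.LA_COLUMNS]
    )
    dictionary = pd.DataFrame(
        {
            "variable": [c for _, c in blocks],
            "block": [b for b, _ in blocks],
            "kind": [
                "categorical" if c in reference.CATEGORICAL_COLUMNS else "numeric"
                for _, c in blocks
            ],
        }
    )
    dic = directory / "Metadata_variables.csv"
    dictionary.to_csv(dic, index=False)
    paths["dictionary"] = dic
    return paths


def read_dataset(path) -> HarmonisedTable:
    """Read back a written dataset CSV into a :class:`HarmonisedTable`."""
    frame = pd.read_csv(
        path, na_values=[MISSING_TOKEN], keep_default_na=False, dtype=str
    )
    frame["Time"] = pd.to_datetime(frame["Time"])
    for col in ("Latitude", "Longitude", "Altitude"):
        frame[col] = frame[col].astype(float)
    for col in reference.VALUE_COLUMNS:
        if col in reference.CATEGORICAL_COLUMNS:
            frame[col] = frame[col].where(frame[col].notna(), None)
        else:
            frame[col] = frame[col].astype(float)
    return HarmonisedTable(frame=frame[reference.ALL_COLUMNS])
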