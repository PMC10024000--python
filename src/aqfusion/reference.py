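"""Reference tables for the extended-Lombardy multi-pollutant monitoring network.

These tables describe the published monitoring network and drive realistic
defaults for the synthetic generators: per-pollutant sensor counts, the
land-use x emission-context station taxonomy, the default daily aggregation
map, the 41-column output schema and the published anomaly exclusion list.
"""

from __future__ import annotations

import pandas as pd

#: Number of sensors per pollutant across the extended Lombardy network
#: (ground-level stations, 2016-2021 period).
SENSOR_COUNTS: dict[str, int] = {
    "pm10": 107,
    "pm25": 54,
    "co": 56,
    "nh3": 10,
    "nox": 110,
    "no2": 136,
    "so2": 40,
}

#: Land-use codes: U = urban, S = suburban, R = rural.
LAND_USE_CODES = ("U", "S", "R")

#: Emission-context codes: B = background, T = traffic, I = industrial.
EMISSION_CONTEXT_CODES = ("B", "T", "I")

#: Cross-classification of the 131 classified stations by land use (rows:
#: U, S, R) and emission context (columns: B, T, I).
STATION_TYPE_COUNTS: dict[tuple[str, str], int] = {
    ("U", "B"): 42, ("U", "T"): 36, ("U", "I"): 3,
    ("S", "B"): 25, ("S", "T"): 1, ("S", "I"): 4,
    ("R", "B"): 18, ("R", "T"): 0, ("R", "I"): 2,
}

#: Output schema: ordered column blocks of the harmonised station x day table.
HEADER_COLUMNS = ["IDStations", "Latitude", "Longitude", "Time", "Altitude"]

AQ_COLUMNS = [
    "AQ_pm10", "AQ_pm25", "AQ_co", "AQ_nh3", "AQ_nox", "AQ_no2", "AQ_so2",
]

WE_COLUMNS = [
    "WE_temp_2m",
    "WE_wind_speed_10m_mean",
    "WE_wind_speed_10m_max",
    "WE_mode_wind_direction_10m",
    "WE_tot_precipitation",
    "WE_precipitation_t",
    "WE_surface_pressure",
    "WE_solar_radiation",
    "WE_wind_speed_100m_mean",
    "WE_wind_speed_100m_max",
    "WE_mode_wind_direction_100m",
    "WE_blh_layer_max",
    "WE_blh_layer_min",
    "WE_rh_min",
    "WE_rh_mean",
    "WE_rh_max",
]

EM_COLUMNS = [
    "EM_nh3_livestock_mm",
    "EM_nh3_agr_soils",
    "EM_nh3_agr_waste_burn",
    "EM_nh3_sum",
    "EM_nox_traffic",
    "EM_nox_sum",
    "EM_so2_sum",
]

LI_COLUMNS = ["LI_pigs", "LI_bovine"]

LA_COLUMNS = ["LA_hvi", "LA_lvi", "LA_land_use", "LA_soil_use"]

#: All value columns in block order (AQ, WE, EM, LI, LA).
VALUE_COLUMNS = AQ_COLUMNS + WE_COLUMNS + EM_COLUMNS + LI_COLUMNS + LA_COLUMNS

#: Full 41-column schema.
ALL_COLUMNS = HEADER_COLUMNS + VALUE_COLUMNS

#: Columns holding categorical values (daily mode aggregation, no numeric
#: formatting on output).
CATEGORICAL_COLUMNS = {
    "WE_mode_wind_direction_10m",
    "WE_mode_wind_direction_100m",
    "WE_precipitation_t",
    "LA_land_use",
    "LA_soil_use",
}

#: Default per-variable daily aggregation functions for the sub-daily inputs.
DEFAULT_AGGREGATION: dict[str, str] = {
    "AQ_pm10": "mean", "AQ_pm25": "mean", "AQ_co": "mean", "AQ_nh3": "mean",
    "AQ_nox": "mean", "AQ_no2": "mean", "AQ_so2": "mean",
    "WE_temp_2m": "mean",
    "WE_wind_speed_10m_mean": "mean",
    "WE_wind_speed_10m_max": "max",
    "WE_mode_wind_direction_10m": "mode",
    "WE_tot_precipitation": "sum",
    "WE_precipitation_t": "mode",
    "WE_surface_pressure": "mean",
    "WE_solar_radiation": "max",
    "WE_wind_speed_100m_mean": "mean",
    "WE_wind_speed_100m_max": "max",
    "WE_mode_wind_direction_100m": "mode",
    "WE_blh_layer_max": "max",
    "WE_blh_layer_min": "min",
    "WE_rh_min": "min",
    "WE_rh_mean": "mean",
    "WE_rh_max": "max",
}

#: Published anomaly exclusion list: extreme concentration values replaced by
#: the missing marker after daily-series construction (explicit list, not an
#: outlier search).
PUBLISHED_ANOMALIES = pd.DataFrame(
    [
        ("STA.IT1582A", "2021-04-27", "AQ_pm10", "extreme value 2399 ug/m3"),
        ("STA.IT2121A", "2021-04-04", "AQ_pm25", "extreme value 2794 ug/m3"),
        ("STA.IT1751A", "2016-10-10", "AQ_so2", "extreme value 152.03 ug/m3"),
    ],
    columns=["station_id", "date", "variable", "reason"],
)


def sensor_total() -> int:
    """Total sensor count across all pollutants in the reference network."""
    return sum(SENSOR_COUNTS.values())


def classified_station_total() -> int:
    """Number of stations with a known land-use x emission-context class."""
    return sum(STATION_TYPE_COUNTS.values())
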