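"""Derived physical variables and unit conversions.

Relative humidity from air and dew-point temperature via the
August-Roche-Magnus approximation, wind speed and 8-point wind-rose
direction from the (u, v) wind components, Kelvin-to-Celsius conversion,
emission flux to daily deposited mass, and livestock density.

All functions are vectorised over numpy arrays and preserve NaN.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "WIND_ROSE",
    "relative_humidity",
    "wind_speed",
    "wind_direction8",
    "kelvin_to_celsius",
    "flux_to_daily_mass",
    "livestock_density",
]

#: Compass categories of the 8-point wind rose, clockwise from North.
WIND_ROSE = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

# Magnus constants, calibrated for temperatures in degrees Celsius.
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # degC


def relative_humidity(temp_c, dew_c, clip: bool = True):
    """Relative humidity in % from air and dew-point temperature (degC).

    RH = 100 * exp( a*T_dew/(b+T_dew) - a*T/(b+T) ) with the Magnus
    constants a = 17.625, b = 243.04 degC.  RH is exactly 100 when the dew
    point equals the air temperature.  A dew point above the air temperature
    is physically inconsistent; it raises a warning and, with ``clip``
    (default), the output is capped at 100.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    dew_c = np.asarray(dew_c, dtype=float)
    if np.any(dew_c <= -_MAGNUS_B):
        raise ValueError(f"dew point at or below {-_MAGNUS_B} degC is singular")
    with np.errstate(invalid="ignore"):
        if np.any(dew_c > temp_c):
            warnings.warn("dew point exceeds air temperature; RH capped at 100",
                          RuntimeWarning, stacklevel=2)
    rh = 100.0 * np.exp(
        _MAGNUS_A * dew_c / (_MAGNUS_B + dew_c)
        - _MAGNUS_A * temp_c / (_MAGNUS_B + temp_c)
    )
    if clip:
        rh = np.minimum(rh, 100.0)
    return rh if rh.ndim else float(rh)


def wind_speed(u, v):
    """Euclidean norm of the wind vector (m/s)."""
    return np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))


def wind_direction8(u, v):
    """8-point wind-rose category of the direction the wind blows FROM.

    The meteorological direction is theta = atan2(-u, -v) (0 deg = northerly
    flow, i.e. wind out of the north), discretised into 45-degree sectors
    centred on the compass points: N covers [337.5, 22.5), NE [22.5, 67.5),
    and so on clockwise.  Calm winds (zero vector) have no direction and
    return None / NaN-style missing.
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    scalar = u_arr.ndim == 0 and v_arr.ndim == 0
    u_arr, v_arr = np.atleast_1d(u_arr), np.atleast_1d(v_arr)
    theta = np.degrees(np.arctan2(-u_arr, -v_arr)) % 360.0
    sector = np.floor(((theta + 22.5) % 360.0) / 45.0).astype(int)
    out = np.array([WIND_ROSE[s] for s in sector], dtype=object)
    calm = (u_arr == 0) & (v_arr == 0)
    out[calm | np.isnan(u_arr) | np.isnan(v_arr)] = None
    return out[0] if scalar else out


def kelvin_to_celsius(temp_k):
    """Convert temperature from Kelvin to degrees Celsius."""
    temp_k = np.asarray(temp_k, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(temp_k < 0):
            raise ValueError("temperature below absolute zero")
    out = temp_k - 273.15
    return out if out.ndim else float(out)


def flux_to_daily_mass(flux):
    """Convert an emission flux in kg m^-2 s^-1 to mg m^-2 per day.

    86400 seconds per day times 1e6 mg per kg.
    """
    flux = np.asarray(flux, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(flux < 0):
            raise ValueError("emission flux must be non-negative")
    out = flux * 86400.0 * 1.0e6
    return out if out.ndim else float(out)


def livestock_density(count, area_km2):
    """Animals per km^2 from a municipal head count and area.

    Missing counts yield missing densities; non-positive areas are invalid.
    """
    area = np.asarray(area_km2, dtype=float)
    if np.any(~np.isnan(area) & (area <= 0)) or np.any(np.isnan(area)):
        raise ValueError("municipal area must be positive")
    count = np.asarray(count, dtype=float)
    out = count / area
    return out if out.ndim else float(out)
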