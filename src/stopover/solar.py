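"""Sunrise/sunset and local solar dates (NOAA solar position algorithm).

Daily movement metrics are computed on daylight fixes only, with the day
defined at local *solar* midnight (timestamps shifted by longitude/15 h).
Sunrise and sunset use the conventional sun-centre altitude of -0.833
degrees (zenith 90.833), which accounts for refraction and the solar disc.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd

ZENITH_DEG = 90.833


def _solar_params(day_of_year: int, hour: float = 12.0) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    gamma = 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return eqtime, decl


def sunrise_sunset(date: dt.date, lat: float, lon: float) -> tuple[dt.datetime, dt.datetime]:
    """UTC sunrise and sunset instants for a calendar date and position.

    During polar day/night the full (empty) civil day is returned so callers
    degrade gracefully at extreme latitudes.
    """
    doy = date.timetuple().tm_yday
    eqtime, decl = _solar_params(doy)
    phi = math.radians(lat)
    cos_ha = math.cos(math.radians(ZENITH_DEG)) / (math.cos(phi) * math.cos(decl)) - math.tan(
        phi
    ) * math.tan(decl)
    midnight = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    if cos_ha >= 1.0:  # polar night
        noon = midnight + dt.timedelta(minutes=720 - 4 * lon - eqtime)
        return noon, noon
    if cos_ha <= -1.0:  # polar day
        return midnight, midnight + dt.timedelta(days=1)
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    return (
        midnight + dt.timedelta(minutes=sunrise_min),
        midnight + dt.timedelta(minutes=sunset_min),
    )


def solar_dates(timestamps: pd.Series, lons: pd.Series) -> pd.Series:
    """Local solar calendar date of each fix (day boundary at solar midnight)."""
    ts = pd.to_datetime(timestamps, utc=True)
    offset = pd.to_timedelta(np.asarray(lons, dtype=float) / 15.0, unit="h")
    return (ts + offset).dt.date
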