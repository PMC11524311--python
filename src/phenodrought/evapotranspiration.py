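"""Monthly Hargreaves potential evapotranspiration (PET).

The Hargreaves equation estimates PET from temperature alone plus
extraterrestrial radiation Ra, which is a deterministic function of
latitude and day of year (FAO-56 formulation).  The monthly value uses
monthly-mean temperatures and mid-month Ra, multiplied by days in month:

    PET_daily = 0.0023 * 0.408 * Ra * (tmean + 17.8) * sqrt(tmax - tmin)

with Ra in MJ m-2 day-1 and 0.408 converting MJ m-2 day-1 to mm day-1 of
equivalent evaporation.  Negative values (tmean below -17.8 degC, common
at the study sites in winter) are clamped to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calendars

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820


def extraterrestrial_radiation(latitude: float, doy) -> float | np.ndarray:
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1 (FAO-56).

    Ra = (24*60/pi) * Gsc * dr * (ws*sin(phi)*sin(delta)
                                  + cos(phi)*cos(delta)*sin(ws))

    with solar declination delta = 0.409*sin(2*pi*doy/365 - 1.39),
    inverse relative Earth-Sun distance dr = 1 + 0.033*cos(2*pi*doy/365),
    and sunset hour angle ws = arccos(-tan(phi)*tan(delta)).  The arccos
    argument is clamped to [-1, 1] so polar day/night degrade gracefully.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(doy)):
        raise ValueError("non-finite latitude or doy")
    phi = np.deg2rad(lat)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        (24.0 * 60.0 / np.pi)
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if ra.ndim == 0 else ra


def hargreaves_pet_monthly(
    year: int,
    month: int,
    tmean: float,
    tmax_mean: float,
    tmin_mean: float,
    latitude: float,
    calendar: str = calendars.NOLEAP,
) -> dict:
    """Hargreaves PET for one month.

    Returns ``{"year", "month", "pet_total", "ra_midmonth"}`` with
    pet_total in mm/month.  Requires tmax_mean >= tmin_mean.
    """
    if tmax_mean < tmin_mean:
        raise ValueError("tmax_mean < tmin_mean")
    mid = calendars.mid_month_doy(year, month, calendar)
    ra = extraterrestrial_radiation(latitude, mid)
    daily = 0.0023 * 0.408 * ra * (tmean + 17.8) * np.sqrt(tmax_mean - tmin_mean)
    daily = max(0.0, float(daily))
    ndays = calendars.days_in_month(year, month, calendar)
    return {
        "year": int(year),
        "month": int(month),
        "pet_total": daily * ndays,
        "ra_midmonth": float(ra),
    }


def pet_series(
    monthly: pd.DataFrame, latitude: float, calendar: str = calendars.NOLEAP
) -> pd.DataFrame:
    """Hargreaves PET for every row of a monthly-climate table.

    ``monthly`` must carry columns year, month, tmean, tmax_mean,
    tmin_mean (as produced by ``climate_io.aggregate_monthly``).
    """
    rows = [
        hargreaves_pet_monthly(
            int(r.year), int(r.month), r.tmean, r.tmax_mean, r.tmin_mean,
            latitude, calendar,
        )
        for r in monthly.itertuples()
    ]
    return pd.DataFrame(rows, columns=["year", "month", "pet_total", "ra_midmonth"])
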