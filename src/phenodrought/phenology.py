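"""Thermal-time bud phenology model.

Budbreak is predicted as the first day of year on which growing
degree-days (GDD) accumulated from January 1 reach a species-class
threshold: 300 degree-days for early-bursting species, 500 for
late-bursting species.  The daily contribution is the daily mean
temperature, (Tmax+Tmin)/2, clamped at 0 degC (base temperature 0).
No chilling requirement is modelled: at the boreal and northern-temperate
sites considered, chilling completion is expected even under warming, so
a pure forcing model is adequate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calendars
from .climate_io import DailyClimateSeries

logger = logging.getLogger(__name__)

#: Sentinel used in tabular outputs for years that never reach a threshold.
NOT_REACHED = -1


@dataclass(frozen=True)
class GddParams:
    """Thermal-time model parameters.

    thresholds maps species class -> degree-day requirement; the defaults
    (early 300, late 500) are the literature values for early- and
    late-bursting species of eastern Canadian forests.
    """

    base_temp: float = 0.0
    start_doy: int = 1
    thresholds: dict = field(
        default_factory=lambda: {"early": 300.0, "late": 500.0}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be strictly positive")


def daily_gdd(tmax: float, tmin: float, base_temp: float = 0.0) -> float:
    """Growing degree-days contributed by one day: max(0, mean - base)."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(~np.isfinite(tmax)) or np.any(~np.isfinite(tmin)):
        raise ValueError("non-finite temperature")
    if np.any(tmin > tmax):
        raise ValueError("tmin > tmax")
    gdd = np.maximum(0.0, (tmax + tmin) / 2.0 - base_temp)
    return float(gdd) if gdd.ndim == 0 else gdd


def cumulative_gdd(
    series: DailyClimateSeries, year: int, params: GddParams | None = None
) -> pd.DataFrame:
    """Cumulative GDD from January 1 for one year: columns doy, cum_gdd."""
    params = params or GddParams()
    grp = series.data[series.data["year"] == year]
    ndays = calendars.days_in_year(year, series.calendar)
    if len(grp) != ndays:
        raise ValueError(f"year {year} incomplete: {len(grp)} of {ndays} days")
    grp = grp.sort_values("doy")
    gdd = daily_gdd(grp["tmax"].to_numpy(), grp["tmin"].to_numpy(), params.base_temp)
    mask = grp["doy"].to_numpy() >= params.start_doy
    gdd = np.where(mask, gdd, 0.0)
    return pd.DataFrame({"doy": grp["doy"].to_numpy(), "cum_gdd": np.cumsum(gdd)})


def budbreak_doy(
    series: DailyClimateSeries, year: int, threshold: float,
    params: GddParams | None = None,
) -> int | None:
    """First DOY whose cumulative GDD reaches ``threshold``; None if never."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cum = cumulative_gdd(series, year, params)
    hit = np.searchsorted(cum["cum_gdd"].to_numpy(), threshold, side="left")
    if hit >= len(cum):
        return None
    return int(cum["doy"].iloc[hit])


def simulate_budbreak(
    series: DailyClimateSeries, params: GddParams | None = None
) -> pd.DataFrame:
    """Budbreak records for every year and species class in a series.

    Returns one row per (year, species_class) with columns
    ``year, site, model, scenario, species_class, doy, month``; years that
    never reach a threshold carry doy = month = NOT_REACHED (-1) and are
    counted in a logged message.
    """
    params = params or GddParams()
    rows = []
    not_reached = 0
    df = series.data
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("doy")
        gdd = daily_gdd(
            grp["tmax"].to_numpy(), grp["tmin"].to_numpy(), params.base_temp
        )
        gdd = np.where(grp["doy"].to_numpy() >= params.start_doy, gdd, 0.0)
        cum = np.cumsum(gdd)
        doys = grp["doy"].to_numpy()
        for cls, threshold in params.thresholds.items():
            hit = np.searchsorted(cum, threshold, side="left")
            if hit >= len(cum):
                doy, month = NOT_REACHED, NOT_REACHED
                not_reached += 1
            else:
                doy = int(doys[hit])
                month = calendars.month_of_doy(int(year), doy, series.calendar)
            rows.append(
                {
                    "year": int(year),
                    "site": series.site_id,
                    "model": series.model_id,
                    "scenario": series.scenario_id,
                    "species_class": cls,
                    "doy": doy,
                    "month": month,
                }
            )
    if not_reached:
        logger.info(
            "simulate_budbreak: %d year/class combinations never reached threshold",
            not_reached,
        )
    return pd.DataFrame(rows)
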