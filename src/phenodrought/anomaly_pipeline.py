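"""Pair budbreak-timing anomalies with drought-index anomalies.

Three-step construction, per stratum (site x model x scenario x species
class), relative to the 1950-1980 historical baseline:

1. identify the calendar month in which budbreak historically occurred
   (the month containing the rounded baseline-mean DOY);
2. average the SPEI of that month over the baseline years -- the
   historical drought exposure at budbreak;
3. for every year, take the difference between that year's budbreak DOY
   and the baseline mean DOY (negative = earlier), and between the SPEI
   of the month containing that year's budbreak and the baseline SPEI
   mean (negative = drier than the historical exposure).

The comparison month follows the year's predicted budbreak, so as
budbreak advances into earlier months the drought exposure is evaluated
there -- the mechanism of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calendars
from .phenology import NOT_REACHED

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = (1950, 1980)

STRATUM_KEYS = ["site", "model", "scenario", "species_class"]


@dataclass(frozen=True)
class BaselineSummary:
    """Historical (baseline-window) budbreak timing and drought exposure."""

    site: str
    model: str
    scenario: str
    species_class: str
    baseline_years: tuple[int, int]
    mean_doy: float
    baseline_month: int
    baseline_spei_mean: float = float("nan")

    @property
    def stratum(self) -> tuple:
        return (self.site, self.model, self.scenario, self.species_class)


def baseline_budbreak(
    records: pd.DataFrame,
    baseline_years: tuple[int, int] = DEFAULT_BASELINE,
    calendar: str = calendars.NOLEAP,
    min_years: int = 5,
) -> list[BaselineSummary]:
    """Baseline mean DOY and month for every stratum in a budbreak table.

    Only years that reached budbreak enter the mean; a stratum with fewer
    than ``min_years`` reached baseline years is an error.  The baseline
    month is the calendar month containing the rounded mean DOY (a
    non-leap/noleap year is used to place it when the mean is fractional).
    """
    lo, hi = baseline_years
    out = []
    for keys, grp in records.groupby(STRATUM_KEYS, sort=True):
        base = grp[
            (grp["year"] >= lo) & (grp["year"] <= hi) & (grp["doy"] != NOT_REACHED)
        ]
        if len(base) < min_years:
            raise ValueError(
                f"stratum {keys}: only {len(base)} reached baseline years "
                f"(need {min_years})"
            )
        mean_doy = float(base["doy"].mean())
        month = calendars.month_of_doy(lo, int(round(mean_doy)), calendar)
        out.append(
            BaselineSummary(
                *keys,
                baseline_years=(lo, hi),
                mean_doy=mean_doy,
                baseline_month=month,
            )
        )
    return out


def baseline_spei(
    spei: pd.DataFrame,
    baseline_month: int,
    baseline_years: tuple[int, int] = DEFAULT_BASELINE,
) -> float:
    """Mean SPEI of one calendar month over the baseline years."""
    lo, hi = baseline_years
    sel = spei[
        (spei["month"] == baseline_month)
        & (spei["year"] >= lo)
        & (spei["year"] <= hi)
    ]
    expected = hi - lo + 1
    if len(sel) != expected:
        raise ValueError(
            f"month {baseline_month}: {len(sel)} of {expected} baseline years present"
        )
    return float(sel["spei"].mean())


def attach_baseline_spei(
    baselines: list[BaselineSummary],
    spei_by_stratum: dict[tuple[str, str, str], pd.DataFrame],
) -> list[BaselineSummary]:
    """Fill baseline_spei_mean from per-(site, model, scenario) SPEI tables."""
    out = []
    for b in baselines:
        spei = spei_by_stratum[(b.site, b.model, b.scenario)]
        mean = baseline_spei(spei, b.baseline_month, b.baseline_years)
        out.append(
            BaselineSummary(
                b.site, b.model, b.scenario, b.species_class,
                baseline_years=b.baseline_years,
                mean_doy=b.mean_doy,
                baseline_month=b.baseline_month,
                baseline_spei_mean=mean,
            )
        )
    return out


def compute_anomalies(
    records: pd.DataFrame,
    spei_by_stratum: dict[tuple[str, str, str], pd.DataFrame],
    baselines: list[BaselineSummary],
) -> pd.DataFrame:
    """Yearly paired anomalies of budbreak DOY and budbreak-month SPEI.

    Returns one row per reached (year, stratum) with columns ``year, site,
    model, scenario, species_class, doy_anomaly, spei_anomaly,
    budbreak_month``.  Not-reached years are skipped with a logged count;
    a missing SPEI value for a needed (year, month) is an error.
    """
    by_stratum = {b.stratum: b for b in baselines}
    rows = []
    skipped = 0
    for r in records.itertuples():
        stratum = (r.site, r.model, r.scenario, r.species_class)
        if stratum not in by_stratum:
            raise ValueError(f"no baseline for stratum {stratum}")
        if r.doy == NOT_REACHED:
            skipped += 1
            continue
        b = by_stratum[stratum]
        spei = spei_by_stratum[(r.site, r.model, r.scenario)]
        sel = spei[(spei["year"] == r.year) & (spei["month"] == r.month)]
        if len(sel) != 1:
            raise ValueError(
                f"missing SPEI for year={r.year} month={r.month} in "
                f"{(r.site, r.model, r.scenario)}"
            )
        rows.append(
            {
                "year": int(r.year),
                "site": r.site,
                "model": r.model,
                "scenario": r.scenario,
                "species_class": r.species_class,
                "doy_anomaly": float(r.doy - b.mean_doy),
                "spei_anomaly": float(sel["spei"].iloc[0] - b.baseline_spei_mean),
                "budbreak_month": int(r.month),
            }
        )
    if skipped:
        logger.info("compute_anomalies: skipped %d not-reached records", skipped)
    return pd.DataFrame(rows)


def standardize(values) -> np.ndarray:
    """z-scores: subtract the mean, divide by the sample (n-1) sd."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd
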