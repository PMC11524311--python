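"""Calendar arithmetic for daily climate series.

Two calendars are supported: the proleptic Gregorian calendar and the
365-day "noleap" calendar common in climate-model output.  Day-of-year
(DOY) is 1-based from January 1 and runs to 365 or 366 depending on the
calendar and year.
"""

from __future__ import annotations

import calendar as _pycal

import numpy as np

GREGORIAN = "gregorian"
NOLEAP = "noleap"

_NOLEAP_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def is_leap(year: int, cal: str) -> bool:
    if cal == NOLEAP:
        return False
    return _pycal.isleap(int(year))


def days_in_month(year: int, month: int, cal: str) -> int:
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if cal == NOLEAP:
        return _NOLEAP_MONTH_LENGTHS[month - 1]
    return _pycal.monthrange(int(year), int(month))[1]


def days_in_year(year: int, cal: str) -> int:
    return 366 if is_leap(year, cal) else 365


def month_of_doy(year: int, doy: int, cal: str) -> int:
    """Calendar month (1-12) containing a given day-of-year."""
    if not 1 <= doy <= days_in_year(year, cal):
        raise ValueError(f"doy {doy} out of range for year {year} ({cal})")
    remaining = int(doy)
    for month in range(1, 13):
        n = days_in_month(year, month, cal)
        if remaining <= n:
            return month
        remaining -= n
    raise AssertionError("unreachable")


def mid_month_doy(year: int, month: int, cal: str) -> int:
    """DOY of the middle day of a month (15th, the library convention)."""
    doy = 0
    for m in range(1, month):
        doy += days_in_month(year, m, cal)
    return doy + 15


def year_month_day_arrays(start_year: int, end_year: int, cal: str):
    """Vectorized (year, month, day, doy) arrays for a span of full years."""
    years, months, days, doys = [], [], [], []
    for y in range(start_year, end_year + 1):
        doy = 1
        for m in range(1, 13):
            n = days_in_month(y, m, cal)
            years.append(np.full(n, y))
            months.append(np.full(n, m))
            days.append(np.arange(1, n + 1))
            doys.append(np.arange(doy, doy + n))
            doy += n
    return (
        np.concatenate(years).astype(np.int64),
        np.concatenate(months).astype(np.int64),
        np.concatenate(days).astype(np.int64),
        np.concatenate(doys).astype(np.int64),
    )
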