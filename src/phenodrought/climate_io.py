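"""Read, validate, write and monthly-aggregate daily climate series.

The on-disk format is a plain CSV with columns ``date,tmax,tmin,prcp``
(ISO-8601 dates, degC, degC, mm/day) preceded by ``#``-prefixed metadata
lines (``# site=``, ``# model=``, ``# scenario=``, ``# latitude=``,
``# calendar=``).  An alternative dialect maps the column names used by
downscaled-CMIP6 portals (``time,tasmax,tasmin,pr``).

Units are fixed at degC and mm/day; no auto-detection is attempted, since
silent unit errors are the dominant failure mode in climate pipelines.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calendars

logger = logging.getLogger(__name__)

#: Column-name mappings per dialect (file name -> canonical name).
DIALECTS = {
    "standard": {"date": "date", "tmax": "tmax", "tmin": "tmin", "prcp": "prcp"},
    "pcic": {"time": "date", "tasmax": "tmax", "tasmin": "tmin", "pr": "prcp"},
}

_DAILY_COLUMNS = ["year", "month", "day", "doy", "tmax", "tmin", "prcp"]


@dataclass
class DailyClimateSeries:
    """One site x model x scenario run of daily Tmax/Tmin/precipitation.

    ``data`` holds one row per calendar day with columns
    ``year, month, day, doy, tmax, tmin, prcp``; rows are strictly
    date-ordered and gap-free under the declared calendar.
    """

    site_id: str
    model_id: str
    scenario_id: str
    latitude: float
    calendar: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.calendar not in (calendars.GREGORIAN, calendars.NOLEAP):
            raise ValueError(f"unknown calendar: {self.calendar!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")

    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].to_numpy())

    def copy_with(self, data: pd.DataFrame) -> "DailyClimateSeries":
        return DailyClimateSeries(
            site_id=self.site_id,
            model_id=self.model_id,
            scenario_id=self.scenario_id,
            latitude=self.latitude,
            calendar=self.calendar,
            data=data.reset_index(drop=True),
        )


def validate_series(series: DailyClimateSeries) -> None:
    """Raise ``ValueError`` on any invariant violation.

    Checks: tmin <= tmax everywhere (offending dates listed), prcp >= 0,
    dates strictly increasing and gap-free within each year under the
    declared calendar.  NaN rows (flagged missing) are exempt from the
    value checks but still occupy their calendar slot.
    """
    df = series.data
    finite = df[["tmax", "tmin", "prcp"]].notna().all(axis=1)
    bad = finite & (df["tmin"] > df["tmax"])
    if bad.any():
        dates = [
            f"{int(r.year):04d}-{int(r.month):02d}-{int(r.day):02d}"
            for r in df[bad].head(10).itertuples()
        ]
        raise ValueError(f"tmin > tmax on {int(bad.sum())} day(s): {', '.join(dates)}")
    neg = finite & (df["prcp"] < 0)
    if neg.any():
        raise ValueError(f"negative precipitation on {int(neg.sum())} day(s)")
    for year, grp in df.groupby("year", sort=True):
        ndays = calendars.days_in_year(int(year), series.calendar)
        doys = grp["doy"].to_numpy()
        if len(doys) == 0:
            continue
        expected = np.arange(doys[0], doys[0] + len(doys))
        if not np.array_equal(doys, expected):
            raise ValueError(f"calendar gap or disorder within year {int(year)}")
        if doys[-1] > ndays:
            raise ValueError(
                f"doy {int(doys[-1])} exceeds calendar length {ndays} in {int(year)}"
            )


def _doy_from_ymd(years, months, days, cal: str) -> np.ndarray:
    out = np.empty(len(years), dtype=np.int64)
    cache: dict[tuple[int, int], int] = {}
    for i, (y, m, d) in enumerate(zip(years, months, days)):
        key = (int(y), int(m))
        if key not in cache:
            cache[key] = sum(
                calendars.days_in_month(int(y), mm, cal) for mm in range(1, int(m))
            )
        out[i] = cache[key] + int(d)
    return out


def read_daily_climate(
    path, dialect: str = "standard", missing_value: float | None = None
) -> DailyClimateSeries:
    """Read a daily climate CSV, validating invariants.

    Rows whose values equal ``missing_value`` are flagged missing (NaN)
    rather than rejected.  Raises ``ValueError`` on unparseable dates,
    tmin > tmax, or calendar gaps.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    rename = {k: v for k, v in DIALECTS[dialect].items() if k in df.columns}
    df = df.rename(columns=rename)
    required = {"date", "tmax", "tmin", "prcp"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")

    cal = meta.get("calendar", calendars.NOLEAP)
    try:
        parts = df["date"].astype(str).str.split("-", expand=True).astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in {path}: {exc}") from exc
    if parts.shape[1] != 3:
        raise ValueError(f"dates must be ISO-8601 YYYY-MM-DD in {path}")
    years, months, days = (parts[i].to_numpy() for i in range(3))

    out = pd.DataFrame(
        {
            "year": years,
            "month": months,
            "day": days,
            "doy": _doy_from_ymd(years, months, days, cal),
            "tmax": pd.to_numeric(df["tmax"]),
            "tmin": pd.to_numeric(df["tmin"]),
            "prcp": pd.to_numeric(df["prcp"]),
        }
    )
    if missing_value is not None:
        for col in ("tmax", "tmin", "prcp"):
            out.loc[out[col] == missing_value, col] = np.nan

    series = DailyClimateSeries(
        site_id=meta.get("site", "unknown"),
        model_id=meta.get("model", "unknown"),
        scenario_id=meta.get("scenario", "unknown"),
        latitude=float(meta.get("latitude", "nan")),
        calendar=cal,
        data=out,
    )
    if not np.isfinite(series.latitude):
        raise ValueError(f"latitude metadata missing or non-finite in {path}")
    validate_series(series)
    return series


def write_daily_climate(series: DailyClimateSeries, path) -> None:
    """Write a series as CSV with commented metadata header lines."""
    path = Path(path)
    df = series.data
    dates = [
        f"{y:04d}-{m:02d}-{d:02d}"
        for y, m, d in zip(df["year"], df["month"], df["day"])
    ]
    out = pd.DataFrame(
        {
            "date": dates,
            "tmax": df["tmax"].to_numpy(),
            "tmin": df["tmin"].to_numpy(),
            "prcp": df["prcp"].to_numpy(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# site={series.site_id}\n")
        fh.write(f"# model={series.model_id}\n")
        fh.write(f"# scenario={series.scenario_id}\n")
        fh.write(f"# latitude={series.latitude!r}\n")
        fh.write(f"# calendar={series.calendar}\n")
        out.to_csv(fh, index=False, float_format="%.17g")


def aggregate_monthly(series: DailyClimateSeries) -> pd.DataFrame:
    """Aggregate a daily series to calendar months.

    Returns a DataFrame with one row per complete (year, month):
    ``year, month, tmean, tmax_mean, tmin_mean, prcp_total, n_days``.
    tmean is the mean over days of (tmax+tmin)/2; prcp_total is the sum.
    Partial months (trailing stubs) and months containing flagged-missing
    days are excluded with a logged warning.
    """
    df = series.data.sort_values(["year", "month", "day"])
    rows = []
    dropped = 0
    for (year, month), grp in df.groupby(["year", "month"], sort=True):
        n_expected = calendars.days_in_month(int(year), int(month), series.calendar)
        complete = len(grp) == n_expected
        has_missing = grp[["tmax", "tmin", "prcp"]].isna().any().any()
        if not complete or has_missing:
            dropped += 1
            continue
        tmean = ((grp["tmax"] + grp["tmin"]) / 2.0).mean()
        rows.append(
            {
                "year": int(year),
                "month": int(month),
                "tmean": float(tmean),
                "tmax_mean": float(grp["tmax"].mean()),
                "tmin_mean": float(grp["tmin"].mean()),
                "prcp_total": float(grp["prcp"].sum()),
                "n_days": int(len(grp)),
            }
        )
    if dropped:
        logger.warning(
            "aggregate_monthly: excluded %d incomplete or missing-flagged month(s)",
            dropped,
        )
    return pd.DataFrame(
        rows,
        columns=["year", "month", "tmean", "tmax_mean", "tmin_mean", "prcp_total", "n_days"],
    )
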