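import numpy as np
import pandas as pd
import pytest

from phenodrought import calendars
from phenodrought.climate_io import DailyClimateSeries
from phenodrought.climate_synth import (
    SynthConfig,
    default_profiles,
    generate_daily_series,
)
from phenodrought.pipeline import PipelineConfig, run_all


def make_series(
    tmax,
    tmin,
    prcp=None,
    start_year=2000,
    calendar=calendars.NOLEAP,
    site="south",
    model="m0",
    scenario="s0",
    latitude=45.33,
):
    """Build a DailyClimateSeries from per-day arrays spanning whole years."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    n = len(tmax)
    ny = 0
    total = 0
    while total < n:
        total += calendars.days_in_year(start_year + ny, calendar)
        ny += 1
    if total != n:
        raise ValueError(f"{n} days does not span whole years from {start_year}")
    years, months, days, doys = calendars.year_month_day_arrays(
        start_year, start_year + ny - 1, calendar
    )
    if prcp is None:
        prcp = np.zeros(n)
    data = pd.DataFrame(
        {
            "year": years,
            "month": months,
            "day": days,
            "doy": doys,
            "tmax": tmax,
            "tmin": tmin,
            "prcp": np.asarray(prcp, dtype=float),
        }
    )
    return DailyClimateSeries(
        site_id=site,
        model_id=model,
        scenario_id=scenario,
        latitude=latitude,
        calendar=calendar,
        data=data,
    )


def random_year_series(rng, start_year=2000, mean=5.0, amp=15.0, noise=4.0):
    """One random noleap year with a seasonal cycle, for oracle tests."""
    doy = np.arange(1, 366)
    tmean = mean - amp * np.cos(2 * np.pi * (doy - 15) / 365) + rng.normal(
        0, noise, 365
    )
    half = rng.uniform(3, 7)
    return make_series(tmean + half, tmean - half, start_year=start_year)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_config():
    """Reduced design (1950-2010, both sites and scenarios, two models)."""
    sites, scenarios, models = default_profiles()
    return SynthConfig(
        start_year=1950,
        end_year=2010,
        sites=tuple(sites),
        scenarios=tuple(scenarios),
        models=(models[1], models[3]),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return run_all(PipelineConfig(synth=small_config))


@pytest.fixture(scope="session")
def sample_series(profiles):
    sites, scenarios, models = profiles
    cfg = SynthConfig(
        start_year=1995, end_year=2004,
        sites=tuple(sites), scenarios=tuple(scenarios), models=tuple(models),
        seed=5,
    )
    return generate_daily_series(cfg, sites[0], scenarios[0], models[0])
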