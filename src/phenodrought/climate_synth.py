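"""Stochastic daily weather generator for two Quebec forest sites.

Emulates downscaled-CMIP6 daily series (Tmax, Tmin, precipitation) for a
southern northern-temperate site and a northern boreal-mixedwood site,
four climate-model variants with differing warming rates (one deliberately
warmest), and two emission scenarios (moderate vs extreme warming),
1950-2100.

Daily mean temperature is a sinusoidal seasonal cycle (minimum near
Jan 15) plus a linear warming trend plus AR(1) noise; Tmax/Tmin bracket
the mean by half the diurnal range.  Precipitation is Bernoulli wet-day
occurrence times Gamma-distributed amounts scaled so the expected annual
total matches the site normal, with month-block trends (wetter winters,
drier summers) applied per scenario.  All randomness derives
deterministically from one root seed and the (site, scenario, model)
labels, so runs are independent but reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import calendars
from .climate_io import DailyClimateSeries

#: Months treated as winter for the precipitation-trend block.
WINTER_MONTHS = (11, 12, 1, 2, 3)


@dataclass(frozen=True)
class SiteProfile:
    """Climate normals and location for one study site."""

    site_id: str
    latitude: float
    longitude: float
    mean_annual_temp: float  # degC
    seasonal_amplitude: float  # degC, half peak-to-peak of the seasonal cycle
    annual_precip: float  # mm/yr
    diurnal_range: float  # degC
    precip_wet_day_prob: float
    label: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")
        if self.seasonal_amplitude <= 0:
            raise ValueError("seasonal_amplitude must be positive")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be non-negative")
        if not 0.0 < self.precip_wet_day_prob <= 1.0:
            raise ValueError("precip_wet_day_prob must be in (0, 1]")


@dataclass(frozen=True)
class ScenarioProfile:
    """Emission scenario: warming rate and seasonal precipitation trends.

    ``precip_trend`` maps calendar month -> fractional change per decade
    in that month's precipitation (positive = wetter).
    """

    scenario_id: str
    warming_rate: float  # degC per decade, linear from start_year
    precip_trend: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelVariant:
    """One climate-model chain, expressed as a warming offset."""

    model_id: str
    warming_offset: float  # degC per decade added to the scenario rate
    noise_seed_offset: int = 0


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults reflect the full study design."""

    start_year: int = 1950
    end_year: int = 2100
    sites: tuple = ()
    scenarios: tuple = ()
    models: tuple = ()
    temp_noise_sd: float = 2.5  # degC, AR(1) innovation sd
    temp_ar1: float = 0.7
    precip_gamma_shape: float = 0.8
    calendar: str = calendars.NOLEAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be non-negative")
        if not 0.0 <= self.temp_ar1 < 1.0:
            raise ValueError("temp_ar1 must be in [0, 1)")

    @classmethod
    def with_defaults(cls, seed: int = 0, **kwargs) -> "SynthConfig":
        sites, scenarios, models = default_profiles()
        kwargs.setdefault("sites", tuple(sites))
        kwargs.setdefault("scenarios", tuple(scenarios))
        kwargs.setdefault("models", tuple(models))
        return cls(seed=seed, **kwargs)


def default_profiles():
    """Default study design: two sites, two scenarios, four model variants.

    Site coordinates and normals are the 1981-2010 weather-station values
    for the two study locations (Magog, south; Lebel-sur-Quevillon, north).
    The canesm5-like variant carries the largest warming offset; the
    gfdl-esm4-like variant the smallest.
    """
    sites = [
        SiteProfile(
            site_id="south",
            latitude=45.33,
            longitude=-72.22,
            mean_annual_temp=5.6,
            seasonal_amplitude=15.5,
            annual_precip=1142.0,
            diurnal_range=10.0,
            precip_wet_day_prob=0.45,
            label="northern temperate forest (Magog)",
        ),
        SiteProfile(
            site_id="north",
            latitude=49.0,
            longitude=-77.00,
            mean_annual_temp=1.0,
            seasonal_amplitude=17.5,
            annual_precip=928.0,
            diurnal_range=10.5,
            precip_wet_day_prob=0.40,
            label="boreal mixedwood forest (Lebel-sur-Quevillon)",
        ),
    ]
    scenarios = [
        ScenarioProfile(
            scenario_id="ssp245",
            warming_rate=0.30,
            precip_trend={m: (0.02 if m in WINTER_MONTHS else -0.02) for m in range(1, 13)},
        ),
        ScenarioProfile(
            scenario_id="ssp585",
            warming_rate=0.55,
            precip_trend={m: (0.03 if m in WINTER_MONTHS else -0.04) for m in range(1, 13)},
        ),
    ]
    models = [
        ModelVariant(model_id="access-cm2", warming_offset=0.05, noise_seed_offset=1),
        ModelVariant(model_id="canesm5", warming_offset=0.15, noise_seed_offset=2),
        ModelVariant(model_id="miroc6", warming_offset=0.00, noise_seed_offset=3),
        ModelVariant(model_id="gfdl-esm4", warming_offset=-0.10, noise_seed_offset=4),
    ]
    offsets = [m.warming_offset for m in models]
    assert offsets.count(max(offsets)) == 1  # exactly one warmest variant
    return sites, scenarios, models


def _stratum_rng(
    config: SynthConfig, site: SiteProfile, scenario: ScenarioProfile, model: ModelVariant
) -> np.random.Generator:
    """Deterministic per-(site, scenario, model) generator from the root seed."""
    key = tuple(
        zlib.crc32(s.encode())
        for s in (site.site_id, scenario.scenario_id, model.model_id)
    )
    ss = np.random.SeedSequence(
        entropy=int(config.seed),
        spawn_key=key + (int(model.noise_seed_offset),),
    )
    return np.random.default_rng(ss)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    burn = 200
    eps = rng.normal(0.0, sd, size=n + burn)
    x = lfilter([1.0], [1.0, -ar1], eps)
    return x[burn:]


def generate_daily_series(
    config: SynthConfig,
    site: SiteProfile,
    scenario: ScenarioProfile,
    model: ModelVariant,
) -> DailyClimateSeries:
    """Generate one site x scenario x model daily series.

    Construction, per day with fractional year t measured from start_year:

    - mean temperature  T = mu + A*cos(2*pi*(doy-15)/L) rotated so the
      minimum falls near Jan 15, plus (warming_rate+offset)/10 * t, plus
      AR(1) noise;
    - Tmax/Tmin = T +/- diurnal_range/2;
    - precipitation = Bernoulli(wet_day_prob) * Gamma(shape, scale) with
      scale chosen so the untrended expected annual total equals the site
      normal, then multiplied by the month's trend factor
      max(0, 1 + trend/10 * t).
    """
    for name, value in (
        ("temp_noise_sd", config.temp_noise_sd),
        ("warming_rate", scenario.warming_rate),
        ("warming_offset", model.warming_offset),
        ("mean_annual_temp", site.mean_annual_temp),
    ):
        if not np.isfinite(value):
            raise ValueError(f"non-finite parameter {name}={value}")

    cal = config.calendar
    years, months, days, doys = calendars.year_month_day_arrays(
        config.start_year, config.end_year, cal
    )
    n = len(years)
    rng = _stratum_rng(config, site, scenario, model)

    ylen = np.array([calendars.days_in_year(int(y), cal) for y in np.unique(years)])
    ylen_by_year = dict(zip(np.unique(years), ylen))
    year_len = np.array([ylen_by_year[y] for y in years], dtype=float)
    t_years = (years - config.start_year) + (doys - 0.5) / year_len

    # seasonal cycle with minimum at doy 15
    phase = 2.0 * np.pi * (doys - 15) / year_len
    seasonal = site.mean_annual_temp - site.seasonal_amplitude * np.cos(phase)
    rate = (scenario.warming_rate + model.warming_offset) / 10.0  # degC/yr
    tmean = seasonal + rate * t_years + _ar1_noise(
        rng, n, config.temp_noise_sd, config.temp_ar1
    )
    half = site.diurnal_range / 2.0
    tmax = tmean + half
    tmin = tmean - half

    wet = rng.random(n) < site.precip_wet_day_prob
    mean_daily = site.annual_precip / (365.0 * site.precip_wet_day_prob)
    scale = mean_daily / config.precip_gamma_shape
    amounts = rng.gamma(config.precip_gamma_shape, scale, size=n)
    trend_by_month = np.array(
        [scenario.precip_trend.get(m, 0.0) for m in range(1, 13)]
    )
    factor = np.maximum(0.0, 1.0 + trend_by_month[months - 1] / 10.0 * t_years)
    prcp = np.where(wet, amounts * factor, 0.0)

    data = pd.DataFrame(
        {
            "year": years,
            "month": months,
            "day": days,
            "doy": doys,
            "tmax": tmax,
            "tmin": tmin,
            "prcp": prcp,
        }
    )
    return DailyClimateSeries(
        site_id=site.site_id,
        model_id=model.model_id,
        scenario_id=scenario.scenario_id,
        latitude=site.latitude,
        calendar=cal,
        data=data,
    )


def generate_all(config: SynthConfig):
    """Yield every (site, scenario, model) series of the configured design."""
    for site in config.sites:
        for scenario in config.scenarios:
            for model in config.models:
                yield generate_daily_series(config, site, scenario, model)
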