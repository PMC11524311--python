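"""End-to-end experiment: simulate -> budbreak -> SPEI -> anomalies -> regress.

One flat configuration drives the full factorial design (2 sites x 2
scenarios x 4 model variants x 2 species classes); all randomness flows
from a single root seed via named substreams, so reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, anomaly_pipeline, climate_io, climate_synth
from . import evapotranspiration, phenology, spei as spei_mod, trend_models

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the experiment once."""

    synth: climate_synth.SynthConfig
    gdd: phenology.GddParams = field(default_factory=phenology.GddParams)
    spei_calibration: tuple | None = None  # None = full series
    baseline_years: tuple = anomaly_pipeline.DEFAULT_BASELINE
    criterion: str = "aic"
    spei_months: tuple = tuple(range(1, 9))

    def __post_init__(self) -> None:
        lo, hi = self.baseline_years
        if not (self.synth.start_year <= lo < hi <= self.synth.end_year):
            raise ValueError("baseline_years must lie within the simulated period")
        if not self.gdd.thresholds:
            raise ValueError("at least one budbreak threshold required")

    @classmethod
    def default(cls, seed: int = 0, **synth_kwargs) -> "PipelineConfig":
        return cls(synth=climate_synth.SynthConfig.with_defaults(seed=seed, **synth_kwargs))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.get("synth", {})
        profiles = {}
        if "sites" in synth_raw:
            profiles["sites"] = tuple(
                climate_synth.SiteProfile(**s) for s in synth_raw.pop("sites")
            )
        if "scenarios" in synth_raw:
            profiles["scenarios"] = tuple(
                climate_synth.ScenarioProfile(
                    scenario_id=s["scenario_id"],
                    warming_rate=s["warming_rate"],
                    precip_trend={int(k): v for k, v in s.get("precip_trend", {}).items()},
                )
                for s in synth_raw.pop("scenarios")
            )
        if "models" in synth_raw:
            profiles["models"] = tuple(
                climate_synth.ModelVariant(**m) for m in synth_raw.pop("models")
            )
        synth = climate_synth.SynthConfig.with_defaults(**{**synth_raw, **profiles})
        kwargs = {}
        if "gdd" in raw:
            g = raw["gdd"]
            kwargs["gdd"] = phenology.GddParams(
                base_temp=g.get("base_temp", 0.0),
                start_doy=g.get("start_doy", 1),
                thresholds={k: float(v) for k, v in g.get(
                    "thresholds", {"early": 300, "late": 500}).items()},
            )
        for key in ("criterion",):
            if key in raw:
                kwargs[key] = raw[key]
        if "spei_calibration" in raw and raw["spei_calibration"] is not None:
            kwargs["spei_calibration"] = tuple(raw["spei_calibration"])
        if "baseline_years" in raw:
            kwargs["baseline_years"] = tuple(raw["baseline_years"])
        if "spei_months" in raw:
            kwargs["spei_months"] = tuple(raw["spei_months"])
        return cls(synth=synth, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class ExperimentBundle:
    """In-memory results of one full run."""

    config: PipelineConfig
    series: dict  # (site, model, scenario) -> DailyClimateSeries
    budbreak: pd.DataFrame
    spei: pd.DataFrame  # columns site, model, scenario, year, month, spei
    anomalies: pd.DataFrame
    baselines: list
    regressions: trend_models.TrendAnalyses


def compute_spei_for_series(
    series: climate_io.DailyClimateSeries,
    calibration: tuple | None = None,
) -> pd.DataFrame:
    """Monthly SPEI table for one daily series (year, month, spei)."""
    monthly = climate_io.aggregate_monthly(series)
    pet = evapotranspiration.pet_series(monthly, series.latitude, series.calendar)
    wb = spei_mod.water_balance(monthly, pet)
    return spei_mod.compute_spei(wb, calibration)


def run_all(config: PipelineConfig, out_dir=None) -> ExperimentBundle:
    """Run every stage on every stratum; optionally write all outputs.

    Stages: climate synthesis, budbreak simulation (both thresholds),
    monthly SPEI, baseline/anomaly construction, and the three trend
    regressions.  Any stage failure aborts with the stage name and the
    offending stratum.
    """
    series_by, bb_parts, spei_parts = {}, [], []
    spei_by_stratum = {}
    for site in config.synth.sites:
        for scenario in config.synth.scenarios:
            for model in config.synth.models:
                key = (site.site_id, model.model_id, scenario.scenario_id)
                try:
                    s = climate_synth.generate_daily_series(
                        config.synth, site, scenario, model
                    )
                    series_by[key] = s
                    bb_parts.append(phenology.simulate_budbreak(s, config.gdd))
                    sp = compute_spei_for_series(s, config.spei_calibration)
                    spei_by_stratum[key] = sp
                    sp = sp.copy()
                    sp.insert(0, "scenario", scenario.scenario_id)
                    sp.insert(0, "model", model.model_id)
                    sp.insert(0, "site", site.site_id)
                    spei_parts.append(sp)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage simulate/spei failed for stratum {key}: {exc}"
                    ) from exc

    budbreak = pd.concat(bb_parts, ignore_index=True)
    spei_df = pd.concat(spei_parts, ignore_index=True)

    try:
        baselines = anomaly_pipeline.baseline_budbreak(
            budbreak, config.baseline_years, config.synth.calendar
        )
        baselines = anomaly_pipeline.attach_baseline_spei(baselines, spei_by_stratum)
        anomalies = anomaly_pipeline.compute_anomalies(
            budbreak, spei_by_stratum, baselines
        )
    except Exception as exc:
        raise RuntimeError(f"stage anomalies failed: {exc}") from exc

    try:
        regressions = trend_models.run_trend_analyses(
            budbreak, spei_df, anomalies,
            criterion=config.criterion, spei_months=config.spei_months,
        )
    except Exception as exc:
        raise RuntimeError(f"stage regress failed: {exc}") from exc

    bundle = ExperimentBundle(
        config=config,
        series=series_by,
        budbreak=budbreak,
        spei=spei_df,
        anomalies=anomalies,
        baselines=baselines,
        regressions=regressions,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _fit_report(name: str, fr: trend_models.FitResult) -> str:
    lines = [
        f"== {name} ==",
        f"response: {fr.response}   n = {fr.n_obs}   R^2 = {fr.r_squared:.4f}   "
        f"{fr.criterion.upper()} = {fr.criterion_value:.2f}",
        f"retained terms: {', '.join(fr.retained_terms) or '(intercept only)'}",
        "coefficients (estimate, se):",
    ]
    for coef, (est, se) in fr.coefficients.items():
        lines.append(f"  {coef:40s} {est:12.5f}  {se:10.5f}")
    if fr.selection_trace:
        lines.append("selection trace (dropped term -> criterion):")
        for term, crit in fr.selection_trace:
            lines.append(f"  - {term:38s} -> {crit:.2f}")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: ExperimentBundle, out_dir) -> None:
    """Serialize a bundle: climate CSVs, records CSVs, report, manifest."""
    out = Path(out_dir)
    (out / "climate").mkdir(parents=True, exist_ok=True)
    for (site, model, scen), s in bundle.series.items():
        climate_io.write_daily_climate(
            s, out / "climate" / f"{site}_{model}_{scen}.csv"
        )
    bundle.budbreak.to_csv(out / "budbreak.csv", index=False)
    bundle.spei.to_csv(out / "spei.csv", index=False, float_format="%.6f")
    bundle.anomalies.to_csv(out / "anomalies.csv", index=False, float_format="%.6f")

    regs = bundle.regressions
    report = [_fit_report("budbreak trend", regs.budbreak_trend)]
    for month, fr in regs.spei_trends.items():
        report.append(_fit_report(f"SPEI trend, month {month}", fr))
    report.append(_fit_report("SPEI trend, pooled months", regs.spei_trend_pooled))
    report.append(_fit_report("anomaly coupling", regs.anomaly))
    (out / "regressions.txt").write_text("\n".join(report))

    coef_rows, trace_lines = [], []
    for name, fr in (
        [("budbreak_trend", regs.budbreak_trend), ("anomaly", regs.anomaly),
         ("spei_pooled", regs.spei_trend_pooled)]
        + [(f"spei_month_{m}", fr) for m, fr in regs.spei_trends.items()]
    ):
        for coef, (est, se) in fr.coefficients.items():
            coef_rows.append(
                {"analysis": name, "term": coef, "estimate": est, "se": se,
                 "r_squared": fr.r_squared, "n_obs": fr.n_obs}
            )
        trace_lines.append(json.dumps(
            {"analysis": name, "criterion": fr.criterion,
             "trace": list(fr.selection_trace),
             "retained": list(fr.retained_terms)}
        ))
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    (out / "selection_trace.jsonl").write_text("\n".join(trace_lines) + "\n")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": bundle.config.synth.seed,
        "config_hash": bundle.config.config_hash(),
        "n_strata": len(bundle.series),
        "n_budbreak_records": int(len(bundle.budbreak)),
        "n_anomaly_records": int(len(bundle.anomalies)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
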