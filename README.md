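# phenodrought

Will climate change make trees burst their buds under drier conditions?
As springs warm, the heat sum that triggers budbreak is reached earlier
in the year — potentially shifting bud burst into months whose water
balance differs from the historical budbreak season. `phenodrought` is a
simulation pipeline for exploring that question for temperate and boreal
forest sites: it generates synthetic daily climate under warming
scenarios, predicts budbreak with a thermal-time model, computes a
monthly drought index, and pairs yearly anomalies of both against a
historical baseline.

It is written for forest ecologists and climate-impact modellers who
want a tested, reproducible implementation of the whole chain rather
than a one-off script.

## The model in brief

- **Budbreak** — thermal-time (growing degree-day) model: budbreak occurs
  on the first day of year `d` with
  `Σ_{t≤d} max(0, (Tmax_t+Tmin_t)/2) ≥ F*`, accumulating from January 1
  with base 0 °C and thresholds `F* = 300` (early-bursting species) and
  `500` (late-bursting species).
- **Drought** — 1-month SPEI: the climatic water balance
  `D = P − PET` (Hargreaves PET, FAO-56 extraterrestrial radiation) is
  fitted per calendar month with a three-parameter log-logistic
  distribution by unbiased probability-weighted moments and mapped
  through the exact standard-normal quantile. Negative SPEI = drier than
  the calibration climatology.
- **Anomalies** — relative to 1950–1980: `Δdoy = doy_year − mean doy`
  (negative = earlier) and `Δspei = SPEI(year, month of that year's
  budbreak) − mean SPEI of the historical budbreak month` (negative =
  drier than historical budbreak conditions).
- **Trends** — OLS with all pairwise interactions and
  marginality-constrained stepwise backward selection (AIC default,
  BIC option): budbreak DOY trends, per-month SPEI trends, and the
  anomaly-on-anomaly regression.

The synthetic generator emulates downscaled-CMIP6 daily series for two
Quebec sites (a southern northern-temperate site at 45.33°N and a
northern boreal-mixedwood site at 49.0°N), four climate-model variants
with differing warming rates (one deliberately warmest), and two
emission scenarios (moderate ssp245 vs extreme ssp585), 1950–2100. See
`docs/methods.md` for every formula, default, and design choice.

## Worked example

```python
from phenodrought import SynthConfig, generate_daily_series, simulate_budbreak
from phenodrought.pipeline import compute_spei_for_series

cfg = SynthConfig.with_defaults(seed=42)
site, scenario, model = cfg.sites[0], cfg.scenarios[1], cfg.models[1]  # south, ssp585, canesm5
series = generate_daily_series(cfg, site, scenario, model)

records = simulate_budbreak(series)
early = records[records.species_class == "early"]
print(early[early.year.isin([1950, 2000, 2100])][["year", "doy", "month"]])

spei = compute_spei_for_series(series)
print(spei[(spei.year == 2100) & (spei.month == 5)])
```

prints

```
     year  doy  month
0    1950  126      5
100  2000  122      5
300  2100   81      3
      year  month     spei
1804  2100      5 -1.04199
```

Under the extreme scenario with the warmest model variant, early-species
budbreak at the southern site advances from day 126 (early May) in 1950
to day 81 (late March) by 2100 — a 45-day advance — while May 2100 sits
about one standard deviation drier than the 1950–2100 May climatology
(SPEI −1.04).

The full experiment (16 site × model × scenario strata, both species
classes, anomalies and all three regressions) runs from one command:

```sh
phenodrought run-all --seed 1 --out runs/demo
```

which writes the climate CSVs, `budbreak.csv`, `spei.csv`,
`anomalies.csv`, a regression report with selection traces, and a
manifest. Reruns with the same seed are byte-identical.

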