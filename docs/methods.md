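# Methods

`phenodrought` simulates whether climate-change-driven advances in spring
budbreak expose trees to drier conditions at the time of bud burst. The
pipeline has five stages: a stochastic daily weather generator, a
thermal-time budbreak model, a monthly drought index (SPEI), an anomaly
construction pairing the two against a historical baseline, and trend
regressions with backward model selection. This note documents the model
in each stage, the parameters that matter, and the design choices made
where the design was genuinely open.

## Thermal-time budbreak model

Budbreak is predicted as the first day of year (DOY) on which growing
degree-days (GDD) accumulated from January 1 reach a species-class
threshold:

    GDD(d) = sum_{t=1..d} max(0, (Tmax_t + Tmin_t)/2)

with base temperature 0 °C and thresholds of 300 degree-days for
early-bursting species and 500 for late-bursting species — the
literature values for temperate/boreal forest trees of eastern Canada.
The daily mean is (Tmax+Tmin)/2, the universal convention when only
max/min are available. The first-crossing rule uses a weak inequality
(the first day the running sum *reaches* the threshold). No chilling
requirement is modelled: at boreal and northern-temperate latitudes,
chilling completion is expected even under strong warming, so a pure
forcing model is adequate; years that never reach a threshold propagate
as missing rather than as a sentinel DOY.

Two invariants follow directly and are enforced by tests: DOY(300) ≤
DOY(500) in every year, and a pointwise-warmer series never delays
budbreak.

## Synthetic climate generator

The generator emulates downscaled-CMIP6 daily series (Tmax, Tmin,
precipitation, 1950–2100) at the statistical level the analysis needs.
It is first-class, tested code — the experiment's study conditions, not
a fixture.

Daily mean temperature is

    T(d) = mu_site - A_site * cos(2*pi*(doy-15)/365) + r/10 * t + e(d)

a single sinusoid with minimum near January 15 (the simplest shape that
reproduces a realistic spring GDD ramp), a linear warming trend of `r`
°C/decade measured from 1950 (matching the linear-regression framing of
the trend analyses), and AR(1) anomalies `e` (innovation sd 2.5 °C,
autocorrelation 0.7, i.e. a stationary daily sd of ~3.5 °C) giving the
inter-annual budbreak variability the analysis requires. Tmax/Tmin
bracket the mean by half the diurnal range.

Precipitation is Bernoulli wet-day occurrence × Gamma(0.8) amounts,
scaled so the expected untrended annual total equals the site normal,
then multiplied by a month-block trend factor (wetter winters
Nov–Mar, drier Apr–Oct) per scenario. Snow is deliberately not
modelled; precipitation is a single phase.

Site defaults are the 1981–2010 weather-station normals for the two
study locations: south (45.33°N, −72.22°W; mean 5.6 °C; 1142 mm) and
north (49.0°N, −77.00°W; mean 1.0 °C; 928 mm). Values no normal fixes
were chosen once as field-realistic: seasonal half-amplitudes 15.5 /
17.5 °C (south/north — boreal winters are relatively colder), diurnal
ranges 10 / 10.5 °C, wet-day probabilities 0.45 / 0.40. Scenario warming
rates are 0.30 °C/decade (moderate, ssp245) and 0.55 °C/decade (extreme,
ssp585), with precipitation trends of +2 / −2 %/decade (winter/summer)
and +3 / −4 %/decade respectively — mid-range CMIP6 values for eastern
Canada. The four model variants differ by a warming offset (+0.15,
+0.05, 0.00, −0.10 °C/decade for canesm5, access-cm2, miroc6,
gfdl-esm4), making exactly one variant distinctly warmest and one least
warm.

All randomness derives from one root seed through substreams keyed by
(site, scenario, model), so strata are independent but the whole
experiment is bit-reproducible. The default calendar is the 365-day
"noleap" calendar common in climate-model output; Gregorian is also
supported throughout the I/O layer.

What the generator does *not* emulate: spatial correlation between
sites, rain-vs-snow partitioning and snowpack, extreme-event clustering,
and any non-linearity in the warming signal. Tests passing on this
synthetic world therefore demonstrate the correctness and the
directional behaviour of the *method*, not a calibrated projection for
these forests.

## Hargreaves PET and extraterrestrial radiation

Monthly potential evapotranspiration uses the temperature-only
Hargreaves equation at monthly resolution, the convention of the
standard drought-index tooling:

    PET_day = 0.0023 * 0.408 * Ra(mid-month) * (Tmean + 17.8) * sqrt(Tmax - Tmin)
    PET_month = max(0, PET_day) * days_in_month

with monthly-mean temperatures and extraterrestrial radiation Ra
evaluated at the 15th of the month. Ra follows the FAO-56 formulation
(solar constant 0.0820 MJ m⁻² min⁻¹; declination
0.409·sin(2π·doy/365 − 1.39); sunset-hour-angle argument clamped to
[−1, 1] so polar day/night degrade gracefully). The 0.408 factor
converts MJ m⁻² day⁻¹ to mm day⁻¹ of equivalent evaporation and is kept
explicit to avoid silent unit bugs. Negative Hargreaves values —
routine at these sites in winter, where Tmean < −17.8 °C — are clamped
to zero. The classic temperature-only Hargreaves form is used (no
precipitation correction).

## SPEI at the 1-month scale

The climatic water balance D = monthly precipitation − monthly PET is
standardized per calendar month: twelve independent fits of the
three-parameter log-logistic distribution

    F(x) = [1 + (alpha/(x - gamma))^beta]^(-1),   x > gamma

by unbiased probability-weighted moments (PWMs) of the ordered
calibration sample,

    w_s = (1/n) * sum_i x_(i) * C(n-i, s) / C(n-1, s)
    beta  = (2 w1 - w0) / (6 w1 - w0 - 6 w2)
    alpha = (w0 - 2 w1) * beta / (Gamma(1+1/beta) * Gamma(1-1/beta))
    gamma = w0 - alpha * Gamma(1+1/beta) * Gamma(1-1/beta)

followed by the *exact* standard-normal quantile of F(D) (not the
classical rational approximation). Probabilities are clamped to
[1e-6, 1−1e-6] so values beyond the calibration support map to bounded,
monotone extremes. Negative SPEI is drier than the calibration
climatology for that month.

Numerical choices worth noting:

- **Calibration window** defaults to the full series (1950–2100) and is
  a first-class configuration knob: calibrating on a sub-window changes
  what "normal" means and therefore how trends read.
- **Left-skewed months.** The log-logistic above carries positive
  L-skewness only; a calendar month whose D sample has non-positive
  L-skewness (possible by sampling noise in near-symmetric months)
  yields an invalid shape and the fit is rejected. The transformer then
  falls back to fitting the negated sample — the opposite-skew member of
  the same generalized-logistic family — and flips the sign of the
  transform. Monotonicity, within-month ranks, and the ~N(0,1)
  calibration distribution are preserved; the fit is flagged
  `mirrored_`.
- Fits are per (site, model, scenario) stratum; pooling across
  scenarios is possible by concatenating inputs but is not the default.

## Baselines and anomalies

The drought exposure question is operationalized in three steps per
stratum (site × model × scenario × species class), relative to the
1950–1980 baseline:

1. the historical budbreak month is the calendar month containing the
   *rounded baseline-mean DOY* — a single month per stratum. (Where
   baseline DOYs straddle two months this is a choice; a modal-month
   alternative would differ by at most one month. At the defaults all
   strata land robustly in May or June.)
2. the baseline drought exposure is the mean SPEI of that month over
   1950–1980;
3. each year's anomalies are `doy_anomaly = DOY_year − mean_DOY_baseline`
   (negative = earlier) and `spei_anomaly = SPEI(year, month containing
   that year's DOY) − baseline mean` (negative = drier than the
   historical exposure). The comparison month *moves with budbreak* as
   it advances — precisely the mechanism under study.

Baseline means use only years that reached budbreak; the DOY-anomaly
baseline is stratum-specific. Standardization for presentation uses
z-scores with the sample (n−1) standard deviation.

## Trend regressions and model selection

Three ordinary-least-squares analyses with treatment-coded categoricals
(alphabetically first level as reference) and all pairwise interactions
among the main terms:

1. budbreak DOY ~ year + model + site + species class + scenario;
2. monthly SPEI ~ year + model + site + scenario, fitted separately per
   calendar month (January–August) plus one pooled fit with month as a
   factor;
3. DOY anomaly ~ SPEI anomaly + site + model + scenario + year +
   species class.

Each model is reduced by stepwise backward elimination on an information
criterion: at every step the term whose removal most lowers the
criterion is dropped, under the marginality constraint that a main
effect is never dropped while a retained interaction contains it; ties
are broken by dropping the lexicographically last candidate, so traces
are deterministic. AIC is the default criterion with BIC as an option.

The selection-identification experiment in the test suite (greedy
backward vs exhaustive search over all hierarchical submodels) is run
under BIC: with AIC's flat 2-unit penalty, roughly a quarter of
simulated datasets sit in near-tie territory where single-step descent
legitimately terminates in a different local optimum than global search
(74% agreement measured, vs 96% under BIC, 100 datasets, 4 main terms,
n = 200). This is a property of greedy stepwise selection, not an
implementation defect, and is why conclusions drawn from the pipeline
are sign/retention checks rather than exact-model claims.

## Problem sizes

The default experiment is the full factorial: 2 sites × 4 model variants
× 2 scenarios × 151 years × 365 days of daily weather (≈0.9 M days),
4,832 budbreak records, 192 per-month SPEI fits, and three
backward-selected regressions; one complete run takes well under a
minute on a single core. Unit tests use reduced spans (typically 10–61
years) chosen so every code path, including the 31-year baseline window,
is exercised.

## Known limitations

- The generator's realism is limited to first- and second-order
  structure (normals, seasonality, AR(1) variability, wet-day/Gamma
  precipitation); it is not a calibrated downscaling product.
- Monthly SPEI cannot separate early- from late-bursting species when
  both burst in the same calendar month — an intrinsic resolution limit
  of a fixed-calendar monthly index. A 30-day moving-window drought
  index anchored on the budbreak date is the natural extension and is
  deliberately not implemented here.
- Single-phase precipitation means rain-on-snow and snowpack depletion
  effects on spring water availability are outside the model.
- Backward selection inherits the usual caveats of stepwise methods;
  retained-term sets should be read qualitatively.
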