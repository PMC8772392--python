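# Methods

This note documents the models, numerical conventions and design choices
behind `heatexposure`. The package estimates heat exposure from gridded
hourly 2-m temperature: urban heat island intensity (UHII) by regression on
urban fraction, Excess Heat Factor (EHF) risk maps against percentile
climatology baselines, and station-based model-evaluation statistics. All
of it is driven and validated by a synthetic meteorology generator with
known injected structure.

## The synthetic generative process

Hourly temperature at time *t* and cell *c* is

    T(t, c) = T0 + A·sin(2π(h(t) − 9)/24)
            + HW(t, c)
            + night(t)·UHII·f(c)
            − L(c)
            + ε,   ε ~ N(0, σ²)

with `T0` the rural daily-mean baseline (default 26 °C), `A` the diurnal
half-amplitude (5 °C; the −9 h phase puts the peak at 15:00 local, a
typical near-surface cycle), `f(c)` the cell's urban fraction and
`night(t)` an indicator for 18:00–06:00 local. Defaults emulate a
Chicago-like mid-summer episode:

| parameter | default | meaning |
|---|---|---|
| `n_days`, `start_date` | 35, 2012-06-04 | episode length; the default heatwave window lands on July 4–7 |
| `hw_amplitude_rural` / `hw_amplitude_urban` | 4.0 / 2.5 °C | additive heatwave pulse on vegetation / urban cells (rural response larger than urban, as observed for this event type) |
| `true_uhii_night` | 2.0 °C | injected nighttime warming per unit urban fraction — the ground truth the UHII regression must recover |
| `lake_cooling_amplitude`, `lake_decay_length` | 5.0 °C, 3 cells | static coastal cooling, exponential decay west of the water band |
| `noise_sd` | 0.3 °C | additive i.i.d. Gaussian noise per cell-hour |
| `climatology_years`, `climatology_days_per_year` | 10, 92 | baseline archive: per-year draws of the non-heatwave process, year seeds `seed + year_index` |

The surface is an idealised coastal city: concentric rings of
industrial/commercial (urban fraction 0.95), high-intensity residential
(0.90) and low-intensity residential (0.50) inside vegetation (0), with the
easternmost columns open water (0). Fractions are categorical, mirroring
NLCD-style class aggregation; water and vegetation always carry fraction 0.

What the generator does **not** emulate: advective dynamics (the lake
breeze is a static field, not a time-varying circulation), humidity and
wind, synoptic day-to-day variability (non-heatwave days are statistically
identical), seasonality inside the 92-day summer pool, and spatially
correlated noise. Passing tests therefore demonstrate the *estimators* are
correct and well-calibrated under a known truth — not that real
WRF/HRLDAS output or station archives satisfy the same assumptions.

## UHII estimation

For each calendar date, hourly values are averaged over the day window
(06:00–18:00 local) and the complementary night window; a night spanning
midnight is labelled by the evening on which it begins, and incomplete
leading/trailing windows are dropped. The per-cell period mean is regressed
on urban fraction by ordinary least squares over all non-water cells
(vegetation cells anchor the zero-fraction end):

    T = URB_FRC · UHII + T(vegetation)

The slope is the UHII in °C per unit fraction, the intercept the vegetation
baseline. The two-sided p-value is the standard t test on the OLS slope and
the 95% CI uses the t quantile with n−2 degrees of freedom. Per-date fits
on period means are the default; a pooled mode (every cell-hour a point)
exists behind a flag and agrees with the default on noise-free input.

Parameter recovery is verified by experiment (`heatexposure.experiments`):
on a 1000-land-cell grid with noise sd 0.3 °C, 100 seeded replicates
recover an injected slope of 2.0 °C with mean error well under 0.05 °C and
~95% CI coverage; with no injected signal the intervals cover zero at the
nominal rate. These experiments switch off the heatwave pulse and the lake
field, which are deterministic confounders correlated with urban fraction
by design — with them on, the fitted slope measures the *combined* spatial
contrast (which is exactly what the full-episode daily series shows: the
apparent nighttime UHII collapses during the heatwave because rural cells
warm more than urban ones).

## EHF mapping

Daily statistics Tmax/Tmin/Tmean are taken over complete 24-hour local
days only (Tmean is the 24-hour arithmetic mean, since the input is hourly;
the (Tmax+Tmin)/2 convention used by some archives is a trivial caller-side
substitution of the daily grids). Each variant defines its own EHF map,
with a variant-matched T95 baseline. The indices, per cell:

    EHI_sig  = T3 − T95
    EHI_accl = T3 − T30
    EHF      = EHI_sig × max(1, EHI_accl)        [°C²]

* **T3** — mean over an explicit list of consecutive event days (default:
  the first three days of the scenario's heatwave window, i.e. July 4–6).
* **T30** — mean over the 30 days ending the day before the first event
  day; a missing day is a hard error, never a partial mean.
* **T95** — per-cell 95th percentile of the multi-year daily climatology,
  linear interpolation between closest order statistics (the rule is
  recorded in the result metadata because percentile conventions shift T95
  by tenths of a degree). At least 20 daily values per cell are required.

Severity: `none` when EHF ≤ 0, `positive` when 0 < EHF ≤ 2 °C², `high`
above 2 °C² (threshold configurable). Open-water cells are masked (NaN in
float fields, code −1 in the severity grid) and never counted.

Two calibration facts worth stating precisely:

* EHF is **not** globally monotone in T3: d(EHF)/dT3 = max(1, accl) +
  sig·1[accl>1], which is negative where EHI_sig < −EHI_accl. Monotonicity
  holds on the heat-risk region EHI_sig ≥ 0, and that is what the property
  test asserts.
* The 95th-percentile baseline is calibrated against *daily values*: a
  fresh year drawn from the climatology process exceeds T95 on ~5% of land
  cell-days by construction. A 3-day mean is less variable than a daily
  value, so its exceedance rate under the null is well below 5% — which is
  why a null episode yields median EHF ≤ 0 rather than a 5% positive rate.

## Station evaluation

Stations are snapped to their nearest cell centre (ties toward the lower
(row, col) index); observed and modelled hourly series are paired on common
timestamps, and unpaired hours are dropped, never interpolated. Metrics per
station: MB = mean(mod−obs), GE = mean|mod−obs|, RMSE = √mean((mod−obs)²).
GE ≥ |MB| and RMSE ≥ |MB| always hold; under pure Gaussian error of sd σ,
GE → σ√(2/π) and RMSE → σ, which the tests verify within 3 standard errors
at n = 10⁵. Aggregation is the unweighted mean across stations. Benchmark
flags compare |MB| and GE to configurable thresholds (defaults 0.5 and
2.0 °C); they are data, not logic.

## Numerical and I/O conventions

* Grids are (row, col), row 0 north; cubes are (time, y, x); times are
  local wall-clock with no attached zone (UTC conversion is the caller's
  ingest-time job).
* NetCDF is written as classic NetCDF-3 via xarray's scipy backend with CF
  layout: hourly time coordinate, `units` attributes, integer-coded land
  classes with flag metadata. Round trips are bit-exact for temperature
  and exact for the integer classes; readers validate dimension order,
  units, fraction range and time-axis regularity, and keep NaN blocks as
  explicit masks with a logged count.
* All randomness descends from one top-level seed: the scenario uses it
  directly, station sampling uses `seed + 10007`, climatology years use
  `seed + year_index`. Identical config + seed reproduce every output file
  byte-for-byte.

## Problem sizes

Default study sizes were chosen so a full validation cycle runs in seconds
on a laptop: 24×28 cells for the demonstration domain, 35-day episodes
(30 pre-event days for T30, the event, and a tail), 10-year × 92-day
climatologies, 1000-land-cell grids × 100 replicates for the recovery
experiments and 2000 land cells for the percentile null calibration. All
sizes are parameters; nothing in the implementation assumes them.

## Known limitations

* The generator's heatwave pulse is a step function in time and space
  (urban vs vegetation); real pulses ramp and mix with advection.
* The nighttime UHI term is a step on the 18:00–06:00 window rather than a
  smooth evening ramp.
* Because the injected UHI is present in the climatology as well as the
  episode, it cancels from EHI_sig; EHF contrasts between urban and rural
  land are then controlled by the heatwave amplitudes (rural > urban by
  default, so rural EHF exceeds urban EHF under the defaults).
* Station observations are cell-snapped with i.i.d. noise — no
  representativeness error, drift or gaps, so MB/GE/RMSE behave exactly
  like their Gaussian theory.
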