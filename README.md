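# heatexposure

Estimating heat exposure from gridded hourly 2-m temperature: urban heat
island intensity (UHII), Excess Heat Factor (EHF) risk maps, and
station-based model-evaluation statistics.

Heatwaves and urban heat islands compound each other: cities stay warm at
night while synoptic heat events can push rural temperatures up even
faster. Epidemiologists and urban climatologists who work with gridded
temperature fields (mesoscale model output, land-data-assimilation
products, downscaled reanalyses) need three things from such fields: a
check that the field matches surface stations, a quantitative UHI measure,
and a spatially resolved heat-stress index. This package provides all
three, plus a synthetic meteorology generator with known injected
structure so every estimator can be validated against ground truth.

## What it computes

**UHII by regression.** Per-cell period-mean temperature (day 06:00–18:00,
night 18:00–06:00 local) is regressed on the cell's urban fraction
`URB_FRC` (0 for water and vegetation, 0.50/0.90/0.95 for the urban
classes) over all non-water cells:

    T = URB_FRC × UHII + T(vegetation)

The slope is the UHII (°C per unit fraction); the intercept is the
vegetation baseline. One fit per date and period, with R, a two-sided
slope p-value, and a 95% CI.

**EHF risk maps.** For each daily statistic (Tmax, Tmin, Tmean):

    EHI_sig  = T3 − T95          (event vs long-term 95th percentile)
    EHI_accl = T3 − T30          (event vs the previous 30 days)
    EHF      = EHI_sig × max(1, EHI_accl)      [°C²]

with T3 the mean over the event days, T30 the 30 days before, and T95 the
per-cell 95th percentile of a multi-year daily climatology. EHF ≤ 0 is
classed `none`, 0–2 °C² `positive`, above 2 °C² `high` severity.

**Station metrics.** Mean bias MB, mean gross error GE and RMSE between
each station's hourly series and its nearest grid cell, with configurable
benchmark flags and an unweighted cross-station aggregate.

## Worked example

```python
from heatexposure import (SyntheticScenario, generate_surface,
                          generate_temperature_cube, daily_uhii_series)

surface = generate_surface(24, 28, lake_cols=3)      # coastal city, 3 water cols
scenario = SyntheticScenario(noise_sd=0.3, seed=42)  # 35 days, HW on July 4-7,
                                                     # injected night UHII 2.0 degC
cube = generate_temperature_cube(surface, scenario)
for est in daily_uhii_series(cube, surface, period="night")[-6:]:
    lo, hi = est.ci95()
    print(f"{est.date.date()}  UHII={est.slope:+.2f} degC  "
          f"95% CI [{lo:+.2f}, {hi:+.2f}]  R={est.r_value:.2f}  p={est.p_value:.1e}")
```

```
2012-07-02  UHII=+1.94 degC  95% CI [+1.74, +2.15]  R=0.61  p=3.4e-61
2012-07-03  UHII=+0.98 degC  95% CI [+0.77, +1.19]  R=0.35  p=1.8e-18
2012-07-04  UHII=+0.02 degC  95% CI [-0.20, +0.24]  R=0.01  p=8.7e-01
2012-07-05  UHII=+0.03 degC  95% CI [-0.19, +0.25]  R=0.01  p=7.6e-01
2012-07-06  UHII=+0.03 degC  95% CI [-0.19, +0.25]  R=0.01  p=8.1e-01
2012-07-07  UHII=+1.00 degC  95% CI [+0.79, +1.21]  R=0.35  p=2.9e-19
```

Before the heatwave the nightly fit recovers the injected 2.0 °C slope
(slightly shaded by the lake-breeze cooling, which overlaps the urban
core). During the July 4–7 event the apparent UHII collapses to ~0: rural
cells warm by 4 °C against 2.5 °C in the city, cancelling the nighttime
urban excess — the same mitigation of UHII by a synoptic heatwave that
motivates fitting the relationship day by day. The nights of July 3 and 7
straddle the window boundary, hence the intermediate ~1 °C slopes.

The same pipeline runs from the shell:

```sh
heatexposure --out-dir demo --seed 42 simulate   # cube.nc, climatologies, stations.csv
heatexposure --out-dir demo --seed 42 evaluate   # metrics.csv
heatexposure --out-dir demo --seed 42 uhii       # uhii_daily.csv, cross_section.csv
heatexposure --out-dir demo --seed 42 ehf        # ehf_{tmax,tmin,tmean}.nc, ehf_summary.csv
heatexposure --out-dir demo --seed 42 report     # report.txt
```

The report for that run prints:

```
Station evaluation (aggregate over stations):
  n pairs 12600  MB -0.003 degC  GE 0.401 degC  RMSE 0.502 degC

Daily UHII (nighttime), 34 days:
  slope mean 1.72 degC, range [0.02, 1.98] degC; min R 0.01

EHF severity (land cells per class):
  tmax: none=0, positive=0, high=600
  tmean: none=0, positive=0, high=600
  tmin: none=0, positive=0, high=600
```

With station noise sd 0.5 °C, the aggregate GE (0.401) sits at the Gaussian
limit σ√(2/π) ≈ 0.399 and RMSE at σ; every land cell is `high` severity
because the event pulse lifts T3 well above every cell's T95. Every run
writes `config_resolved.yaml` beside its outputs; re-running from that
config and seed reproduces all files byte-for-byte.

See `docs/methods.md` for the generative model, estimator details,
calibration facts and known limitations.

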