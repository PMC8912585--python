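# evipheno

Satellite-derived phenology of Mediterranean semi-deciduous shrublands:
EVI time-series cleaning, extraction of 13 growth-cycle metrics, and
attribution of their year-to-year variation to lagged climate windows.

## The problem

Drought semi-deciduous shrubs such as *Phlomis fruticosa* run a complex
annual cycle: a high, stable canopy through winter, a massive **spring drop**
of winter leaves before the summer drought, a low-canopy **dry period**, and
an abrupt **autumn revival** when the first rains rehydrate the summer
leaves. The cycle is visible in the Enhanced Vegetation Index

    EVI = 2.5 (R_nir − R_red) / (R_nir + 6 R_red − 7.5 R_blue + 1)

computed from 8-day surface-reflectance composites (46 per year, start
days-of-year 1, 9, …, 361). This package implements, for ecologists working
with such series, the full analysis chain:

1. **Cleaning** — BISE (Best Index Slope Extraction) forward-scan rejection
   of cloud-depressed composites, then Fourier-harmonic smoothing with an
   upper-envelope adjustment (`evipheno.evi`).
2. **Phenology metrics** — per year and site: spring-drop onset/end/duration
   (SDO, SDE, SDD) and autumn-revival onset/end/duration (ARO, ARE, ARD)
   where the first derivative of the smoothed curve leaves / re-enters a
   near-zero band; dry-period onset/end/duration (DPO, DPE, DPD) where EVI
   crosses a threshold (default 0.3, the midpoint of the long-term
   extremes); annual max/min EVI and their dates (`evipheno.phenology`).
3. **Site comparison** — per-metric means, differences, paired *t*-tests.
4. **Climate drivers** — 93 lagged window predictors per event (`VAR_n_lag`:
   mean temperature T, precipitation total Pr, or rain-day count RD over
   *n* = 1–6 consecutive months ending *lag* = 0–5 months before the event),
   screened by Pearson correlation and fitted by forward–backward stepwise
   multiple linear regression with a VIF collinearity guard; monthly EVI is
   additionally modelled by a random forest with a 64/16/20
   train/validation/test split (`evipheno.climate`).
5. **Trends** — per-metric OLS slopes against calendar year.
6. **Synthetic data** — a ground-truthed generator (double-logistic annual
   curves, cloud-biased noise, seasonal climate, climate-coupled event
   dates) so every stage is testable without satellite downloads
   (`evipheno.synthetic`).

A `PipelineConfig`-driven orchestrator (`evipheno.pipeline`) and an
`evipheno` command-line tool tie the stages together over CSV inputs.

## Worked example

```python
from evipheno import (CurveConfig, ClimateConfig, gen_coupled_dataset,
                      bise_correct, fft_smooth, extract_all_metrics, trend_fit)
from evipheno.synthetic import default_driver_coupling

series, daily, truth = gen_coupled_dataset(
    CurveConfig(seed=1), ClimateConfig(seed=2), default_driver_coupling(3),
    n_years=21, site_id="xeric")
smoothed = fft_smooth(bise_correct(series))
metrics = extract_all_metrics(smoothed)
print(metrics[["year", "sdo", "sde", "sdd", "dpo", "dpe", "max_evi", "min_evi"]].head(5))
t = trend_fit(metrics.set_index("year")["sdo"], name="sdo")
print(f"sdo trend: {t.slope:+.2f} days/year (p = {t.p:.2f}, n = {t.n_years})")
```

prints

```
 year   sdo   sde   sdd   dpo   dpe  max_evi  min_evi
 2000  93.0 204.0 111.0 152.0 303.0 0.458684 0.191493
 2001  75.0 207.0 132.0 152.0 301.0 0.455326 0.187640
 2002  93.0 217.0 124.0 160.0 303.0 0.449264 0.193129
 2003 103.0 208.0 105.0 157.0 302.0 0.458065 0.193155
 2004 102.0 209.0 107.0 158.0 304.0 0.449708 0.178261
sdo trend: +0.03 days/year (p = 0.95, n = 21)
```

Each row is one year's phenology: leaf fall starts around DOY 75–103
(March–April), canopy drops below the 0.3 threshold in late May
(DOY ≈ 152–160), and the dry period ends with the autumn rains around
DOY ≈ 302. With no embedded trend, the fitted SDO slope is ≈ 0 and not
significant. Against the generator's ground truth, the detected onsets here
have a median absolute error of ≈ 4 days — half a composite.

The same analysis from the shell:

```sh
evipheno simulate --outdir data --site xeric --years 21 --seed 1
evipheno preprocess --evi-csv data/xeric_evi.csv --out data/xeric_smoothed.csv
evipheno phenology --smoothed-csv data/xeric_smoothed.csv --out data/xeric_metrics.csv
evipheno trends --metrics-csv data/xeric_metrics.csv --out data/xeric_trends.csv
```

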