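# stlur — space-time land-use regression for NO₂ exposure

`stlur` implements the time-space NO₂ exposure-modelling workflow used in
birth-cohort air-pollution epidemiology, where health effects of interest are
tied to short, dated windows (pregnancy trimesters, the first weeks of life)
and an annual-average land-use regression (LUR) surface is not enough.  The
workflow was developed for the Bernese passive-sampler networks: a rural
network (~101 sites, consecutive 14-day Palmes-tube periods, 1998–2009) and
an urban network (~45 sites, calendar-month periods), validated externally
with 14-day Passam measurements at cohort participants' homes.

The core model is an intercept-free multivariable regression on the log
scale,

```
log(NO₂) = Σᵢ βᵢ X_is  +  Σⱼ βⱼ X_jt
```

with spatial covariates `X_s` (land-use fractions, road lengths, traffic and
population in 50–1000 m buffers, distance to the nearest major road, annual
dispersion-model NO₂, altitude) and temporal covariates `X_t` (period means
of background-station NO₂ and meteorology, an ordinal season code, a
year/year² trend).  No intercept is used because the background terms carry
the baseline; R² is therefore computed manually about the observed mean.
Variables are chosen by an iterative thematic-group stepwise procedure with
a 1-percentage-point R² rule and printed tie-breaks, validated by ten-fold
cross-validation with refit coefficients, and the final models are published
as per-IQR coefficient tables that this package can consume directly for
prediction.

Because the original Swiss monitoring and GIS data are not deposited, the
package ships a first-class synthetic-region generator whose ground truth
reuses the model's own generative form — so coefficient recovery, CI
coverage, CV consistency, backyard-bias recovery and selection recovery are
all exactly testable.

## Worked example: the published rural model as a prediction engine

```python
import datetime as dt
from stlur import load_bern_table, predict_no2, per_iqr_effect

table = load_bern_table("rural")          # parsed per-IQR coefficient table
atoms = {a.strip() for v in table.variables for a in v.split("*")}
values = {a: 0.0 for a in atoms if a != "season"}
values.update({
    "log(aqm_no2)": 2.62, "log(dispersion_no2)": 3.08,
    "road_major_len_100": 197.0, "sqrt(traffic_nearest_road)": 12.5,
    "pop_100": 103.3, "altitude": 535.0, "temperature": 9.75,
    "boundary_layer_height": 319.7, "lu_lowdens_200": 0.999,
    "road_major_len_1000": 197.0, "road_major_len_500": 197.0,
    "year": 0.0, "square(year)": 0.0,     # trend baseline excluded, see below
})
period = (dt.date(2004, 3, 1), dt.date(2004, 3, 15))   # supplies season = 2
log_no2, no2 = predict_no2(table, values, period=period)
print(f"log NO2 (excl. trend baseline) = {log_no2:.3f}")
print(f"per-IQR effect of log(aqm_no2): {per_iqr_effect(table, 'log(aqm_no2)'):+.3f}")
print(f"per-IQR effect of temperature:  {per_iqr_effect(table, 'temperature'):+.3f}")
```

prints

```
log NO2 (excl. trend baseline) = 1.516
per-IQR effect of log(aqm_no2): +0.250
per-IQR effect of temperature:  -0.102
```

The per-IQR effects reproduce the published table entries exactly: moving
the background-station term across its interquartile range raises log NO₂ by
0.250; a warmer period lowers it by 0.102.  The time-trend polynomial is set
to zero here because the printed table's raw-scale back-transformation of
that near-collinear pair is ill-conditioned (see `docs/methods.md`);
contrasts and per-IQR effects are unaffected.

Exposure windows for a cohort participant:

```python
from stlur import pregnancy_windows, window_exposure
windows = pregnancy_windows(dt.date(2004, 1, 15), dt.date(2004, 10, 20))
# window_exposure(period_predictions, windows[0]) -> day-weighted mean NO2
```

## The synthetic workflow end to end

```python
import numpy as np
from stlur import (rural_config, generate_region, generate_measurements,
                   fit_terms, parse_term, kfold_cv, manual_r2)

cfg = rural_config(seed=11)               # 101 sites, 14-day periods, 1998-2009
region = generate_region(cfg)
meas, pred = generate_measurements(region)          # ~24.5k measurements
terms = [parse_term(k) for k in cfg.truth_coefficients]
y = np.log(meas.no2.to_numpy())
fit = fit_terms(terms, pred, y)
oof = kfold_cv(terms, pred, y, k=10, seed=3)
print(fit.r2, manual_r2(y, oof))          # e.g. 0.534 0.534
```

A `stlur` console command exposes the same steps
(`simulate`, `features`, `fit`, `select`, `crossval`, `predict`); see
`stlur --help`.

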