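# Methods

## The model

Measured NO₂ concentrations from passive samplers integrate over an exposure
period (14 days in the rural network, calendar months in the urban one).
For each region a single multivariable regression is fit on the log scale
with the intercept suppressed:

```
log(NO₂) = Σᵢ βᵢ X_is + Σⱼ βⱼ X_jt + ε,    ε ~ N(0, σ²)
```

The baseline is carried by near-constant covariates (the dispersion-model
background, the time-trend polynomial), which is why no intercept is used.
Spatial covariates are computed once per site and calendar year; temporal
covariates are period means of daily series.  The fit is ordinary least
squares through the origin, solved by SVD; standard errors use σ̂² = RSS/(n−p)
and 95 % CIs the t distribution with n−p degrees of freedom (no intercept, p
design columns).  Because regression software does not report R² for a
through-origin fit, the coefficient of determination is computed manually as
1 − SSE/SST with SST about the observed mean; this keeps it comparable with
conventional (intercept-including) LUR models and can be negative for a
model worse than the mean.

### Terms and transforms

Model terms are written in a small canonical grammar
(`log(aqm_no2)`, `sqrt(vehicles_100)`, `square(year)`,
`road_major_len_100 * season` for a space-time interaction).  `log` and
`sqrt` enforce their domains and name the offending rows.  A natural-cubic
spline basis (3 df, quantile knots, linear tails) exists for linearity
diagnostics during selection only; final models never carry spline terms.

Season enters as a numeric ordinal (1 summer May–Aug, 2 mid-season
Mar/Apr/Sep/Oct, 3 winter Nov–Feb), coded on the period midpoint; a period
straddling a boundary takes its midpoint's season.  This ordinal coding —
rather than two dummies — matches how the final models report a single
estimate with percentiles 1/2/3.

The time trend is the decimal year of the period midpoint, entered raw
together with its square.  Centring the pair was considered and rejected:
with no intercept in the model, centring is not prediction-invariant (the
centring constant has nowhere to go), and double-precision SVD handles the
conditioning of the raw pair at these magnitudes.

## Spatial predictors

All buffer aggregates use exact geometric clipping on closed discs of the
standard radii 50/100/200/300/500/1000 m (the disc polygon uses 64 segments
per quadrant; relative area error ~10⁻⁴, well below test tolerances):

* land-use fraction per class: area(class ∩ disc)/area(disc), coded 0–1 so
  that published "per 0→100 %" land-use estimates are raw coefficients;
* major-road length: clipped polyline length (highways + major roads);
* vehicles in buffer: the summed AADT of distinct segments intersecting the
  disc.  The source tables do not disambiguate a count-of-vehicles versus an
  AADT×length "traffic load" definition; the count definition is isolated
  behind one function so it can be swapped;
* population: grid counts weighted by cell∩disc area fraction;
* nearest major road: Euclidean distance floored at 5 m (so log(1/d) stays
  finite for on-road sites) plus the argmin segment's traffic;
* dispersion NO₂: the containing 400 m cell of the annual grid.

Layers available for several source years (traffic counts, land-use class,
dispersion grids) are linearly interpolated to the calendar year of the
period midpoint and held constant beyond their first/last source year.
Geometry is computed once per site; only attributes vary across years.

## Temporal predictors

Daily series (background NO₂ from one rural AQM station; temperature,
pressure, humidity, wind, cloud, radiation, boundary-layer height from the
nearest of three meteorological stations, by Euclidean distance) are
averaged over [period_start, period_end).  A period must have ≥ 80 % of its
days present, otherwise a missing-data error identifies the gap; the
threshold is a package choice, as source completeness rules are not
standardised.

## Variable selection

Candidates are organised in thematic groups (land use, traffic, roads,
topography, dispersion NO₂, AQM NO₂, meteorology, population), each with an
a-priori base variable; the base model has one term per group.  The
procedure then iterates forward/swap steps within groups and backward
elimination until a full pass accepts no change (cap 20 iterations,
non-convergence reported in the trace):

* a forward addition or swap is accepted when it improves model R² by at
  least 1 percentage point and does not worsen the ten-fold CV R²;
* a term is removed when removal costs less than 1 point of both
  (the fewer-variables rule);
* among alternatives within 1 point, the tie-break order is: fewer
  variables → buffer radius similar to one already in the model → most
  linear dependency (the identity-transform variant loses < 1 point against
  its best transform) → no transformation.

After the main effects converge, space-time interactions — products of one
spatial and one temporal model term — are tested greedily: all candidate
products are scored and the best is added while it clears the same
acceptance rule.  Greedy scoring matters in practice: seasonal covariates
(background NO₂, season, temperature) are mutually correlated, and taking
the first passing product instead of the best one can admit a proxy
interaction in place of the true one.  Every decision, accepted or not, is
logged with the rule invoked; with a fixed seed (which only fixes the CV
folds) the trace is exactly reproducible.

The coefficient report scales each β by the interquartile range of its
design column (the transformed scale on which the term enters), with
land-use fractions reported per 0→1 instead because their IQR is typically
zero; terms are ordered by greedy forward addition maximising adjusted R²,
with the cumulative adjusted R² attached.  Percentiles use linear
interpolation between order statistics.  An interaction's IQR is that of
the product column.

## Validation

Internal: ten-fold CV over a seeded random partition of observations (not
sites; site-blocked CV would be the conservative alternative and is noted
as such).  The term set is fixed, coefficients are refit per fold, and each
observation is predicted exactly once out-of-fold.  Metrics — Pearson r,
manual R², and (concentration scale only) RMSE — are computed on the log
scale and on concentrations by exponentiating predictions without
retransformation bias correction, matching how the original models were
reported.  Bland–Altman agreement regresses (predicted − observed) on the
pair means.

External: each residence measurement is routed to the rural or urban model
by its region tag.  Backyard-placed samplers under-read; the correction
factor per region is exp(mean log-residual of non-backyard − mean
log-residual of backyard), applied multiplicatively to backyard measured
concentrations — applying the recovered factor removes the stratum
difference in mean log residuals by construction.  Quartile agreement uses
linear-weighted Cohen's κ (weights 1 − |i−j|/3) with both vectors cut at
the observed vector's quartiles.

## The synthetic generator

The generator emulates the study conditions, not Swiss geography: a planar
square region (30 km rural / 7 km urban), random road network in three
classes with AADT spanning more than two orders of magnitude and source
years 2000/2004/2008, an exhaustive non-overlapping land-use tiling for
2000 and 2006, a population grid, 400 m annual dispersion grids 2000–2007
driven by traffic proximity, one background AQM station and three
meteorological stations with daily series 1998–2012 (winter-high background
NO₂, summer-high temperature and boundary-layer height, AR(1) day-to-day
noise).  Sites are placed by the networks' published typology shares
(near-highway, near-major-road, background, …).

Ground truth is the model's own form: log concentrations are Σβ·X plus
N(0, 0.2) noise, exponentiated; backyard measurements are divided by the
region's factor (defaults 1.275 rural, 1.104 urban, the values the original
study estimated).  Default coefficient magnitudes echo the published
models' per-IQR effects; a near-constant raw-year column plays the baseline
role of the suppressed intercept, and the year² term is omitted from the
default truth (see below).  Campaign sizes reproduce the study scale:
101 sites × 312 biweekly periods at 78 % completeness ≈ 24.5k rural
measurements (median ≈ 27 µg/m³, right-skewed); 45 sites × 108 months at
90 % ≈ 4.4k urban measurements.  Medians and spreads were calibrated once
to the reported descriptive statistics when the defaults were fixed.

What passing tests on this world do **not** show about real data: there is
no terrain or meteorological physics (nearest-station assignment ignores
topographic barriers), no spatial or temporal autocorrelation in the noise
(the original estimation also ignored it), no sampler measurement error
beyond the log-normal residual, and the generating model is exactly the
fitted model family — so recovery results certify the machinery, not the
realism of any particular coefficient.

## Numerical choices and degenerate inputs

* SVD solver with rank guard at σ_min/σ_max < 10⁻¹⁰; rank deficiency names
  the suspect columns.
* Distance floor 5 m before reciprocal/log transforms.
* Quartile binning for κ fails loudly when ties empty an observed bin.
* `manual_r2` raises on zero observed variance; `adjusted_r2` requires
  n > p + 1.
* Exposure windows require ≥ 80 % day coverage; trimesters are gestational
  weeks 1–13, 14–27, 28–delivery (the week cut-offs are a package choice).
* Interaction per-IQR effects hold partners at zero for main effects and
  scale the product column for interaction rows.

## The published year polynomial

The shipped rural/urban coefficient tables back out raw β as estimate/IQR.
For the year/year² pair this back-transformation is ill-conditioned: the
implied raw pair (+0.098 per year, −2.6×10⁻⁵ per year²) nets to ≈ +93 log
units at year ≈ 2004, two orders larger than log NO₂ itself, so the original
fit must have handled the polynomial on a shifted scale that the printed
table does not preserve.  Consequently absolute predictions from the
printed tables are meaningful only up to the trend baseline; per-IQR
effects, CIs, orderings and all contrasts round-trip exactly and are what
the package asserts.  This is also why the synthetic truth uses a plain
year term as its baseline instead of the full polynomial.

## Problem sizes used in checks

Full-scale campaigns (~24.5k rural, ~4.4k urban) for fitting, CV and
backyard recovery; 200 replicate campaigns of ~2000 measurements for CI
coverage; a 40-site, 3-year scene (~2.5k measurements, 50 noise replicates)
for selection recovery; 100 random small problems for the OLS oracle; 450
residence sites (half backyard) for the correction factors.
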