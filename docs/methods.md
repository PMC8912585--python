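# Methods

This note documents the models, parameter choices, and numerical conventions
behind `evipheno`, and what the synthetic-data experiments do and do not
demonstrate about real satellite series.

## Composite calendar and day arithmetic

All series live on the standard 8-day compositing calendar: 46 composites
per year with start days-of-year 1, 9, …, 361; the final composite absorbs
day 365/366. Dates are composite *start* dates. Multi-year arithmetic uses a
nominal 365-day year, so a day-of-year above 365 denotes a date in the
following calendar year (370 = 5 January). Monthly assignment of composites
and of daily climate uses real (leap-aware) calendar dates. The two
conventions can disagree by at most one day around leap years, far below the
8-day sampling interval.

## Cleaning

Cloud contamination biases composite EVI *low*, never high. Cleaning
therefore has two asymmetric stages.

**BISE forward scan.** A point is examined when it drops by more than
`bise_min_drop_fraction` (default 0.2) of the last accepted value — the
classic "strong artificial decrease" trigger. It is rejected as a cloud
artefact when, within the next `bise_slide_composites` composites (default
5, ≈ 40 days), some value recovers at least `bise_recovery_fraction`
(default 0.2) of the drop: genuine senescence does not rebound that fast.
Rejected points are replaced by linear interpolation between accepted
neighbours. The minimum-drop trigger is what makes the operation idempotent:
the steepest genuine seasonal decline in these systems loses under ~10% of
the canopy signal per composite, so real phenology is never re-examined on a
second pass.

**Harmonic smoothing.** The full multi-year series is projected on a Fourier
basis retaining the constant term plus all harmonics at ≤ `n_harmonics`
cycles/year. Each of `envelope_iterations` (default 2) passes doubles the
weight of points lying *above* the current fit and refits by weighted least
squares, pulling the reconstruction toward the upper envelope and
compensating residual (sub-trigger) cloud depression. With zero envelope
iterations the projection is computed by FFT truncation and is exactly
mean-preserving; retaining all 23 harmonics/year reproduces the input to
machine precision.

`n_harmonics` defaults to 5. The choice is a bias–variance compromise
measured on the generator's ground truth: at 4 harmonics/year the ~77-day
autumn revival is under-resolved, displacing its detected end by ≈ +6 days
systematically and lowering the spring peak derivative on which the
detection band is based; at 6 the extra noise passband dominates. With 5,
the median absolute event-recovery error under the default noise model is
≤ 7 days for all four derivative-based events (it exceeds 10 days for the
autumn-revival end at 4).

## Event detection

**Derivative events.** The first derivative is estimated by central
differences (one-sided at the ends), in EVI per composite step. Within a
seasonal search window (spring: DOY 1–240; autumn: DOY 210–400, wrapping
into the next year), the near-zero band is ± `deriv_epsilon_fraction` times
the window's maximum absolute derivative. The transition is the run of at
least `min_run` (default 2) composites beyond the band that *contains the
window's peak derivative* — on clean data this is identical to the first
qualifying run, but under noise the literal first run can fire on plateau
wiggles weeks early. Onset and end are the band-crossing times, linearly
interpolated between the bracketing composites and rounded to whole days;
pure grid-snapping would add a systematic half-composite (+4 day) ceiling
bias, half the one-composite error budget.

`deriv_epsilon_fraction` defaults to 0.19, derived in closed form from the
transition convention: the generator (and the package's reading of
onset/end) places onset at 5% and end at 95% of a logistic transition's
amplitude, and a logistic's derivative stands at 4 × 0.05 × 0.95 ≈ 0.19 of
its peak exactly at those points. A band at 10% of the peak would fire at
the 2.6% amplitude point — ~14 days early at typical spring spans — and no
one-composite recovery claim could hold. Sensitivity: between 0.15 and 0.25
the noiseless round-trip moves by under 4 days per event; the 0.19 value
keeps it centred.

**Threshold events.** The dry period is delimited by interpolated crossings
of `dry_threshold` (default 0.3): onset at the first downward crossing after
the annual maximum, end at the first upward crossing after the subsequent
minimum, searched as far as the following spring (`min_search_end_doy`,
default DOY 485). The 0.3 default is the midpoint between the long-term
maximum and minimum EVI of these shrublands; `compute_threshold` recomputes
that midpoint for any series as an alternative. One robustness rule: when
smoothing overshoot places the calendar-year maximum *after* the summer
trough (so no crossing can follow it), the scan restarts from the pre-summer
(DOY ≤ 182) maximum. Reported annual extrema always use the literal
calendar-year maximum; the annual minimum is searched between the maximum
and the following spring, ties resolved to the earlier date.

## Site comparison

Metrics are paired by year; years missing a value in either site are
dropped pairwise per metric. Differences are means (site a − site b) with
two-sided paired *t*-tests; fewer than 3 complete pairs leaves the p-value
missing, an exactly zero difference vector reports p = 1, and a constant
nonzero difference (zero variance) is flagged with p = 0.

## Climate windows and driver attribution

Daily station records are aggregated to monthly mean temperature (T, °C),
precipitation total (Pr, mm), and rain-day count (RD, days with
≥ `rain_day_min` mm; default 1.0 mm — a common synoptic convention). A month
missing more than 20% of its days is treated as missing.

A window predictor `VAR_n_lag` aggregates one variable over *n* consecutive
months ending *lag* months before the target month (lag 0 includes the
target month). The default family is *n* = 1–6 at lag 0 plus *n* = 1–5 at
lags 1–5, i.e. 31 windows per variable, 93 in total. For phenology
responses, windows are anchored at the month containing the event's
long-term mean date — anchoring at per-year dates would let the response
leak into its own predictor definition.

Attribution is a two-stage screen-then-select procedure. The Pearson screen
ranks windows by |r| (two-sided p-values); the candidate list reserves each
variable's top 3 windows before filling to `top_k` = 10 by overall rank.
The reservation matters: windows of one variable are strongly
inter-correlated (adjacent temperature windows at r ≈ 0.7–0.85), so a single
strong driver otherwise floods the list with near-duplicates of itself and
competing variables never reach the regression. Forward–backward stepwise
OLS then enters candidates at p < 0.05, removes at p > 0.10, and drops any
candidate whose variance inflation factor against the current model exceeds
10 before each entry. All three thresholds are conventional and exposed.

Monthly EVI gets two models: the best two-window linear model by adjusted R²
among the screened candidates, and a random forest on all 93 windows with a
random 64/16/20 train/validation/test split (floor rounding on train and
validation, remainder to test). The validation split picks tree count and
minimum leaf size over a small grid (default 250/500 trees × leaf 1/3/5);
the model is refitted on train+validation and reported with test R², test
RMSE, and the top-10 permutation importances on the test months. Below 50
usable months the split is refused and an out-of-bag evaluation runs
instead. `compare_models` reports both skills and how many MLR-selected
windows appear in the forest's top-10.

Interannual trends are ordinary least squares of a yearly metric on calendar
year (slope in days/year or EVI/year), two-sided p, requiring ≥ 3 years; an
exactly constant series reports slope 0, p = 1.

## Synthetic generator

The generator emulates the study design end to end so that every stage can
be validated against recorded truth.

**Annual curve.** A double logistic between a winter plateau (`max_evi`,
default 0.45) and a summer trough (`min_evi`, 0.18): a falling branch
centred between spring-drop onset and end and a rising branch centred
between autumn-revival onset and end, rates set so each transition spans its
5%–95% amplitude points exactly between the configured onset and end DOYs
(defaults 95–212 and 268–345, a xeric coastal shrubland). The 5–95%
convention is what makes the detection band's 0.19 default principled (see
above). Because the revival is only 95% complete at the year boundary,
adjacent years interact at the ~3 × 10⁻³ EVI level; interior years of a
constant-configuration stack are translation-identical to machine precision.

**Observation noise.** Additive Gaussian noise (`noise_sd`, default 0.01)
plus cloud dropouts: with probability 0.1 a composite is depressed by a
uniform draw from 0.05–0.2 EVI. Dropouts are negative-only by construction,
which is exactly the asymmetry the BISE trigger and the upper-envelope
smoothing exploit.

**Climate.** Daily temperature is an annual cosine (mean 17.9 °C, amplitude
8 °C, peak DOY 208 — a coastal Mediterranean regime) plus AR(1) daily noise
(SD 2 °C, φ = 0.7) and a per-month interannual anomaly (SD 1 °C). Each day
rains with its month's probability (wet winters, near-dry summers) and
amounts are gamma(0.8, 10 mm), giving ≈ 730 mm/year. The cosine period
equals the actual year length so every annual mean is exact.

**Coupling.** True event dates are base + Σ coefficient × (window anomaly)
+ trend × year-index + Gaussian residual (default SD 4 days); years drawn
out of order are redrawn from a fresh sub-seed. The canonical
driver-recovery configuration (`default_driver_coupling`) couples the
spring-drop onset to the anchor month's precipitation (−0.3 day/mm) and to
the mean temperature of the two preceding months (+10 day/°C). These
magnitudes were set by a power calculation: they give effect SDs of ≈ 9.6
and ≈ 7.5 days against the 4-day residual at n = 21 years, i.e. marginal
correlations ≈ 0.6–0.75, the level at which joint stepwise selection of both
windows (or their one-month-shifted neighbours) succeeds in ≥ 90% of
replicates. Weaker couplings are scientifically plausible but make the
recovery experiment a test of statistical power rather than of the
selection machinery.

**What passing does and does not show.** The generator reproduces the data
*structure* — compositing calendar, curve shape, cloud asymmetry, seasonal
climate, linear climate coupling — but not everything about real data:
no soil-background or sensor drift, no spatially correlated multi-pixel
noise, no missing composites beyond dropouts, single-station climate without
measurement error, and an exactly double-logistic curve family. Recovery
results therefore validate the pipeline's correctness and its noise
robustness under the stated model, not the remote-sensing error budget of
any particular sensor product.

## Test-design notes

Two statistical checks are designed for valid reference distributions. The
Pearson-screen calibration runs null responses against the 18 single-month
windows (each variable at lags 0–5), which share no months within a
variable; pooling all 93 overlapping windows would correlate the rejection
indicators (≈ the squared window correlation) and inflate the fraction's
sampling SD ≈ 2.4-fold beyond the binomial band used as the reference. The
MLR-vs-forest comparison couples monthly EVI to two *temperature* windows
plus their product: with both drivers in one variable family, the linear
pair, the forest's importance ranking, and their overlap are stable, while a
cross-variable interaction makes the best linear pair a phase-mixture proxy
that neither model family ranks consistently.

Simulation sizes (5 × 21-year datasets for event recovery, 100 replicates
for driver recovery and screen calibration, 200 for trend recovery) were
chosen so that each check's Monte-Carlo error is small against its
tolerance while the whole suite stays interactive.

## Known limitations

- Derivative events are only meaningful when one dominant transition exists
  per search window; double dips within a window are attributed to the
  excursion containing the peak derivative.
- The epsilon band scales with the *observed* window peak derivative, so
  severe smoothing attenuation shifts detected onsets slightly; this is the
  main residual error term in the recovery experiments.
- Stepwise selection with 93 collinear candidates at n = 21 is intrinsically
  unstable between neighbouring windows; results should be read at
  month-resolution, not window-identity resolution.
- The mean-month anchoring of phenology windows discards within-year timing
  variation; per-year anchoring is easy to add but conflates response and
  predictor timing.
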