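# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `phenotherm`, in the order the pipeline uses
them.

## Temperature compensation

All response families return a non-negative rate per hour; negative
values are clipped after evaluation (including the Wang–Engel model
outside its cardinal range).  The compensation integral is a left-step
(rectangle) sum on the covariate grid — the recorded temperature holds
until the next record — matching hourly logger data; public cumulative
values are divided by 24 so thermal time reads in °C·d.  A fine-grid
trapezoid quadrature exists only as a test oracle; on diurnal courses the
hourly step sum agrees with it to well under 0.5%.  Inversion (which
instant reaches a compensated target) interpolates linearly within the
crossing step, which is exact because the cumulative is piecewise linear
in time.  Timestamps are timezone-naive local time throughout.

The bilinear family is the max of three expressions,
`max(T/T_min·r_min, r_min + (T−T_min)·a, 0)`.  This shape is only the
intended "slow start below T_min, slope a above" when `T_min > 0` and
`a ≥ r_min/T_min`; construction rejects `T_min ≤ 0` and warns when the
slope condition fails (the max-of-three form then develops a kink
artifact).  Rather than silently reparametrizing, the fitting code
parametrizes `r_min` relative to its kink-free ceiling `a·T_min`.

Species-level thermal time uses literature base temperatures: 0 °C
(winter wheat), 5 °C (soybean), configurable.

## Likelihoods

**Tracker data** (dense rates, one uninterrupted series per leaf) are
used raw — no smoothing — with measurement error modelled as a stationary
Gaussian AR(p) process, p ∈ {0, 1, 2, 3}.  The likelihood is exact: a
multivariate-normal term for the first p residuals of each series (the
stationary autocovariance from the Yule–Walker equations) plus
conditional innovations; the innovation variance is profiled out.
Stationarity is enforced by optimizing partial autocorrelations through a
tanh map and the Durbin–Levinson recursion.  The mean parameters and AR
parameters are optimized jointly (Nelder–Mead over a bounded, gap-
parametrized vector so `T_min < T_opt < T_max` by construction), warm-
started from a multi-start iid least-squares stage.  Orders are compared
by BIC with k = (free mean parameters) + p + 1.  Identifiability guards:
at least 50 observations per fitted unit and a temperature spread of at
least 5 °C (base temperature and slope are not separable at constant
temperature).

**Sparse trait series** (plant height, canopy cover) are fitted through
increments: the predicted increment between consecutive measurement dates
is the difference of the compensation integral under the candidate
parameters, with iid Gaussian errors.  Monotone P-spline smoothing
(I-spline basis with non-negative coefficients, second-order difference
penalty) is available for height series but off by default on synthetic
data.  The optimizer screens a coarse start grid, refines the best starts
with Nelder–Mead and polishes with trust-region least squares; the SSE
surface has shallow secondary minima in the cardinal temperatures.  A
practical caveat verified in simulation: cardinal temperatures are only
identified where the season actually samples the response — a spring-only
window leaves `T_max` essentially unconstrained, so recovery experiments
use a full April–mid-August window.

## Semiparametric responses

The hierarchical spline regresses rate on temperature with a shared
P-spline basis (uniform knots extended beyond the data range, so the
second-difference penalty's null space is exactly the linear functions):
a population curve plus per-genotype and per-replication deviation
curves.  Deviations carry an additional ridge penalty so they shrink to
zero under the null of no genotype differences; smoothing and ridge
weights are selected by GCV on a small log grid.

The neural response is a [1, 5, 5, 1] sigmoid trunk trained on pooled
data (Adam, initial learning rate 0.05, exponential decay γ = 0.996,
batch size 2000, 1,500 pretraining epochs), then extended by an
unactivated genotype head and fine-tuned (≤ 800 epochs, early stopping
with patience 40 and minimum improvement 1e-4 on a 9:1 train/validation
split).  The head is parametrized as deviations from the shared trunk,
`out_g = (1 + Δw_g)·trunk(T) + Δb_g`, with the L1 penalty on (Δw, Δb):
an infinite penalty therefore collapses all genotypes onto the shared
curve, which is the behaviour one wants from "regularize the genotype
layer".  Training is float64 throughout; all randomness (initialization,
split, batch order) derives from one seed and the loss trajectory is
hashable for reproducibility checks.

## Growth validation

Increment prediction accuracy is assessed with a random-regression mixed
model: `Δy_ijkt = r_it (μ + g_i + v_j) + b_j + e`, where `r_it` is the
compensated increment under the response model being tested, μ is the
fixed overall slope, `g_i` and `v_j` are random genotype and year slope
deviations, and `b_j` a fixed per-year offset (the year offset enters
additively, not through `r`, and is treated as fixed).  Predictions use
`r_it μ` for cultivar-level models and `r_it (μ + ĝ_i)` for species-level
models and thermal time, where the genotype BLUP slope supplies the
cultivar's intrinsic rate.  Metrics are computed against the 1:1 line and
never clamped; pooling is per cultivar and overall.  Splits keep whole
series (one leaf, one plot) on one side; year-based cross-validation
holds out each year once.

## Mixed-model machinery

Both mixed models run on a dense REML engine written for field-trial
scale: variances are optimized on the log scale with L-BFGS from two
deterministic starts, and the marginal covariance `V = σ²_e I + Z D Z'`
is handled through the Woodbury identity on pre-computed cross-products,
so one likelihood evaluation costs O(q³) in the number of random-effect
columns (tens) rather than O(n³).  Variance estimates that collapse to
the numerical floor are reported as exactly zero and flagged as boundary
estimates; their BLUPs are zeroed.  The engine reproduces
`statsmodels.MixedLM` REML estimates on shared test problems to four
decimals.

## Phenology G×E decomposition

A phenology period is linearized under a response model and decomposed as
`y_ijk = μ + v_j + g_i + (vg)_ij + e_ijk` with fixed year effects, a
random genotype effect and random genotype-by-year effects with a
*diagonal* variance structure (one interaction variance per year).  The
reported `σ²_vg` aggregates the year-specific variances by their mean
(configurable to sum); `pct_gxe = 100·σ²_vg/(σ²_vg + σ²_g)`.  Spearman
correlations compare year-specific predictions `v_j + g_i + (vg)_ij`
against the overall `g_i`; when all interaction BLUPs in a year are zero
the correlation is defined as 1 (no rank changes).  Optional iid
row/range/row×range random effects absorb spatial trends; they are off by
default because the generator simulates no field layout.

**Normalization.**  Cultivar-level models yield durations on
genotype-specific scales (each genotype's parameters carry their own rate
units), so durations must be normalized before variances are compared.
Two schemes are provided.  `genotype_mean` divides by each genotype's
sample mean ("scaled to one per genotype").  In a *balanced* design this
makes the genotype main effect exactly collinear with the scaling
constraint: every genotype's sample mean is one, REML necessarily
estimates σ²_g = 0, and the G×E share degenerates to {0, 100} — a fact
easily verified by planting known variance components.  The pipeline
therefore defaults to `rate_unit` normalization: durations are divided by
the model's intrinsic rate unit (its mean response over a 0–30 °C
reference grid), which removes exactly the units artifact while leaving
real earliness differences in σ²_g.  Under species-level models the
divisor is common to all genotypes, so the choice only matters for
cultivar-level models.  Mean-one scaling remains available for unbalanced
data and comparability displays.

Calendar-day residuals invert the compensation integral: the predicted
duration for genotype i is `(μ + ĝ_i + mean_j v̂_j)` times the genotype's
normalization divisor, pushed through the year's own temperature series
from the observed period start; periods whose prediction is unreachable
within the series are dropped, never imputed.

Jointing onset can be estimated from height series by the quarter-of-
maximum-elongation-rate rule: the earliest date the smoothed elongation
rate reaches 25% of its seasonal maximum (finite differences between
consecutive smoothed points, linear interpolation between interval
midpoints; a constant-rate series is flagged degenerate).

## Environmental indices

Thornthwaite PET: monthly `16 K (10T/I)^a` with the annual heat index I
and day-length correction K from latitude and solar declination; months
at or below 0 °C get zero; daily values by division; the heat index is
computed per calendar year with a monthly-climatology fallback for
incomplete years.  SPI fits rolling 30-day precipitation sums with a
zero-inflated gamma (mixture weight = zero-sum frequency, gamma by ML);
SPEI fits the water balance `P − PET` with a three-parameter log-logistic
by probability-weighted moments.  Because the log-logistic is inherently
right-skewed and simulated 30-day balances can be mildly left-skewed, a
negative PWM shape triggers fitting the reflected series with the
complementary probability — same family, both skew directions.
Distribution fitting pools the whole record rather than per-calendar-day
climatology: the records here are short (4–7 years), and the indices are
used as within-period anomaly summaries, not operational drought
monitors.  The standard orientation (positive = wet) is used; a
`sign_flip` flag inverts it for conventions that read positive values as
dry.  Cold stress is `Σ max(0, −t_min)` over the period (positive
magnitude); extreme features sum SPI/SPEI values beyond ±1 and ±1.75;
periods are half-open `[t1, t2)` so adjacent periods tile additively.

The lasso attribution centers and scales features, runs λ over a 60-point
log grid from 1e-8 to 5 (α = 1) and selects λ by repeated 5-fold CV (10
repeats) minimizing MSE, computed efficiently with one warm-started
coordinate-descent path per fold.  CV-minimal λ is prediction-optimal but
not selection-consistent — it habitually retains small spurious
coefficients — so a one-standard-error rule (`rule="1se"`, SE taken
across the repeat-level CV estimates) is provided for workflows where the
support itself is the result.  Constant residuals return the null model.

## The synthetic generator

The generator defines the study conditions and is itself tested code.
Hourly air temperature = annual mean 9.5 °C + seasonal sinusoid
(amplitude 8.5 °C, peak mid-July) + diurnal sinusoid (amplitude 4.5 °C,
peak 15:00) + a synoptic AR(1) anomaly on the daily scale (sd 3 °C,
day-to-day persistence 0.75, linearly interpolated to hours) + hourly
AR(1) noise (sd 0.5, φ 0.8) + a year offset (sd 1 °C).  The synoptic
component matters: year-specific cold and warm spells are the physical
source of the G×E signal that a mismatched response model manufactures.
Soil temperature is an exponentially smoothed, damped and offset copy of
air temperature — a filter contract, not a heat-transport model.  Daily
precipitation is Bernoulli(0.45) occurrence × gamma(0.8, 8 mm) amounts
(long-run ≈ 2.9 mm/day); radiation is a clear-sky seasonal curve shaded
on wet days.

Cultivars draw parameters around species means: `r_max` varies
log-normally (sd 0.12) in both modes; in `per_se` mode the shape
parameters also vary (asymptotic: T_min sd 1.2 °C, s sd 0.35; Wang–Engel:
cardinal temperatures sd 1.5 °C), spans comparable to reported base-
temperature differences among temperate cultivars.  Stage thresholds are
genotype-fixed compensated amounts (vegetative 14, generative 16,
maturity 20 in per-day response units, ±10% genotype variation): each
stage date is the inversion of the genotype's own compensation integral,
chained from a season start of 1 March (a surrogate for spring growth
resumption — winter dynamics, vernalization and photoperiod are
deliberately outside the model).  Observed dates get uniform ±1 day
jitter, reflecting scoring granularity; the latent chain is never
jittered, so a zero-jitter scenario round-trips exactly.  Trait series
observe the scaled integral plus iid noise (sd 6 mm at a 30 mm-per-unit
scale) on ~11 random dates; canopy cover is capped at 100%.  All
randomness flows from one seed through named substreams (weather,
cultivars, thresholds, tracker, trait, phenology), so a configuration
regenerates byte-identical data.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: photoperiod and vernalization responses,
tillering/branching and lodging confounders between trait levels, spatial
field gradients (row/range support exists in the model but no layout is
simulated), disease pressure, and sensor-specific artifacts beyond AR
noise.  Transfers between trait levels (organ → canopy) that the field
literature finds difficult are not represented.

## Problem sizes and defaults

The shipped experiments run at the scale of the emulated field study:
wheat 12 cultivars × 6 years × 2 replications (432 period observations,
144 per stage), tracker series of 841–5,000 rate observations, 11 height
dates × 2 reps × 5 years for recovery experiments, 50 simulated years for
index calibration, and 20-seed replicate batches for stochastic claims;
stochastic recovery claims are summarized by medians across seeds.
G×E percentages under these conditions are small in absolute terms (the
generator's interaction signal is a few percent of a compensated
duration); the *contrast* between model levels, not the absolute
percentage, is the reproducible quantity.

## Known limitations

- The AR likelihood treats the tracker observable as rates; position-
  level integration of the error process is not modelled.
- Increment errors are assumed independent; autocorrelation in platform
  series is expected to be handled by prior smoothing.
- The unstructured genotype/year slope covariance of the validation model
  is reduced to independent slope variances (identifiable at synthetic
  scale); an unstructured 2×2 extension is a natural follow-up.
- Supra-optimal behaviour of the asymptotic family is undefined by
  design; use Wang–Engel where decline above the optimum matters.
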