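# Methods

`snakeburden` estimates national snakebite mortality and burden from
verbal-autopsy (VA) surveillance of the Million Death Study type: a large,
nationally representative sample of small geographic sampling units in which
every death is recorded and independently assigned an ICD-10 cause by two
physicians. This note documents the models, their assumptions, the defaults,
and the design decisions taken where the procedure was genuinely open.

## Record classification and plausible bounds

A death is a *confirmed* snakebite when both physicians coded X20 (contact
with venomous snakes). Records where at least one physician used X20, X27
(other venomous animals) or X29 (unspecified venomous animal/plant), without
dual agreement on X20, are *candidates* resolved by an explicit review table;
in synthetic pipelines the generator's true cause plays the role of the
study's symptom/keyword re-examination, deliberately avoiding any modelling
of the review itself. The dual-coding pattern yields plausible bounds on the
snakebite count: the lower bound requires immediate agreement, the central
count adds review-confirmed candidates, and the upper bound admits any
candidate with a single X20 code plus review-eligible X27/X29 pairs. Whether
a lone X27/X29 code should already count toward the upper bound is ambiguous
in the source tables; the default says no, and `include_x29_alone=True`
selects the wider reading. These three rules are run through the whole rate
pipeline to propagate coding uncertainty, and they are monotone by
construction.

## From deaths to rates

Sampling weights (probability of selection, by rural/urban stratum) convert
record counts to weighted cause fractions per stratum (year × 5-year age
band by default). Weighted death *frequencies* — numerator and denominator
separately, never the ratio — are smoothed with a 3-year backward moving
average; smoothing counts rather than ratios preserves envelope conservation
exactly. Lag weights default to equal thirds because no published lag scheme
exists; they are configurable. Edge years renormalize over the lags actually
available, so the first year of a frame equals its own unsmoothed value.
Strata with no deaths are interpolated linearly along year within stratum
(nearest value at the edges) and flagged; a stratum with no observations at
all stays missing and is reported.

Fractions are multiplied into an external all-cause death envelope (playing
the role of UN Population Division totals) per year and age band; by
construction the all-cause fractions reproduce the envelope exactly. Rates
are deaths over person-years; age standardization uses a bundled
India-2001-census-like standard population (weights normalized to one, so
rescaling the standard is a no-op). The cumulative risk of dying of
snakebite before age 70 is the additive approximation
`5 × Σ(rates over the 14 bands 0–4 … 65–69) / 10^5`, expressed in percent; at
snakebite magnitudes it differs from the exponential survival form
`1 − exp(−Σ)` by under 0.001 percentage points, and the additive form is what
the published tables use. Annual series are smoothed/projected with a cubic
regression spline (three interior knots at year quantiles — the smallest
default that can bend twice over a dozen years) whose terminal segment is
continued linearly outside the data range; a global cubic is inside the
spline space, so polynomial series are reproduced to machine precision.

## Seasonality and altitude

Daily death counts are pooled by day of year into a composite year (Feb 29
folded into Feb 28) and fitted with a Poisson GLM on harmonic terms; two
harmonics by default, because a single sinusoid cannot represent the
asymmetric single-peak monsoon shape. With a log link and an intercept the
fitted curve sums exactly to the observed total; an optional rescaling maps
the within-year shape to a national annual total estimated elsewhere. Flat
data are reported as flat (peak/trough ratio within 2% of one) rather than
with a spurious peak day. The monsoon share is the count fraction in
June 1 – September 30 (122/365 ≈ 0.334 under uniformity). Altitude profiles
aggregate deaths and person-years to 100 m bins at the sampling-unit level
(one altitude per unit) and report crude rates and cumulative death shares.

## National rates and geostatistical risk mapping

Two Bayesian Poisson models with log link:

1. **National age-sex rates** — one parameter per age×sex cell (no global
   intercept), a linear year trend centred on the 2010 reference, offset log
   person-years, ages 0–69 in 5-year bands. Cells without exposure are
   dropped with a warning. Priors are weak normals (SD 10) on log rates.
2. **Geostatistical relative risk** — unit deaths `y_i ~ Poisson(E_i·RR_i)`
   with `E_i` the expectation under the national rates, and
   `log RR_i = x_i'β + f(s_i) + e_i`: covariates (rural flag, female
   illiteracy *in rural units only*, altitude in km, long-term mean
   temperature; centred and scaled), a Gaussian process `f` with Matérn
   covariance of smoothness 1 (well-behaved in two dimensions and standard in
   disease mapping), and iid unit effects `e`. Coefficient priors are
   N(0, 2.5²) on the standardized scale.

Inference is empirical-Bayes MAP with a Laplace approximation: the three
field hyperparameters (spatial SD, range in degrees, unit-effect SD)
maximise the Laplace-approximate marginal likelihood (Nelder-Mead on the log
scale; each evaluation is an inner Newton solve for the joint mode of
coefficients and latent field, with step halving). Credible intervals come
from the curvature at the mode; hyperparameter intervals from a
finite-difference Hessian of the evidence. An ensemble-MCMC mode (emcee, at
the fitted hyperparameters) serves as a cross-check of the Gaussian
approximation on small problems; the two modes agree on posterior median RR
within 10% on the test fixtures.

Grid prediction kriges the spatial component to cell centres — the iid unit
effect is deliberately excluded, being unit noise rather than place — and
combines kriging variance with parameter uncertainty. Absolute risk is the
predicted RR times the national risk-before-70, cellwise, so ratios of
absolute risks equal ratios of RRs exactly. Population-at-risk sums a
population raster over cells exceeding each threshold (0.6% and 1% by
default) and refuses to combine grids whose geometry differs rather than
resampling silently. All grids are regular lon-lat grids exchanged as long
CSV tables (row, col, lon, lat, value); cell centres, row-major from the
south-west corner.

One caveat documented deliberately: multiplying all populations and deaths
by a constant is *not* an exact invariance of a hierarchical Bayesian model,
because the information content of the likelihood changes and shrinkage
relaxes. The property holds in the data-dominated limit, which is what the
tests assert (median log-RR shift below 0.05, correlation above 0.99, with
hyperparameters held fixed).

## Case fatality and indirect prevalence

The pooled in-hospital case-fatality rate (CFR) is the slope of deaths on
bites across literature studies, through the origin (no bites must imply no
deaths; a free-intercept variant exists behind a flag), restricted to study
types reporting both quantities. Outliers are removed in a single pass when
their standardized residual exceeds 3; residuals are standardized by a
size-dependent scale (variance proportional to bites, as for count
outcomes) so large studies are not flagged merely for having large absolute
residuals — with a constant scale the rule preferentially trims big studies
and biases the slope on clean data. Back-calculation: in-hospital bites =
estimated hospital deaths / CFR; total bites scale by one plus the
out-of-hospital:in-hospital ratio per scenario; a fixed envenomation share
(default 0.70) splits totals into envenomations and dry/non-venomous bites.
The scenario grid is explicit user input (the published assumption table is
not reproducible here); the shipped examples are labelled illustrative.

## Surveillance coverage

Per region, estimated hospital deaths = estimated total deaths × in-hospital
fraction, and coverage = reported deaths / estimated hospital deaths. The
national aggregate always uses summed numerators and denominators, never
averaged percentages. Two rounding modes exist because published tables
round cells computed from unrounded intermediates: comparisons against
published numbers should use raw mode with one-unit-in-the-last-digit slack.

## The synthetic generator

The generator emulates the survey's structure with a known truth so every
estimator has a recovery test: ~7,400 geocoded units by default (tests use
hundreds), 94% rural population share, log-normal unit populations (mean
3,000, matching ~23 million people over ~7,600 units), a fixed young age
pyramid shared by all units, a Matérn GP log-RR field sampled on a coarse
grid and interpolated to units, population-weight-centred covariate effects,
a log-scale annual sinusoid for seasonality (amplitude 0.66 by default,
giving a monsoon share near one half and a peak/trough ratio near 3.7 with a
mid-July peak; `amplitude_for_monsoon_share` solves for a target share), 92%
dual-coder agreement on true snakebite deaths, 23% in-hospital deaths, and
interleaved other-cause deaths from a fixed ICD-10 list. Unit relative risks
are normalized so their population-weighted mean is exactly one, which makes
the base rate directly recoverable. The all-cause envelope is emitted as the
generator's own expectation, playing the role of external demographic
totals.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: verbal-autopsy narrative quality and
physician behaviour beyond the two-code agreement process, state-level
administrative structure, spatially structured undercounting, weather-driven
year-to-year seasonality shifts, and publication bias in the literature
tables beyond a plantable outlier fraction.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen to exercise
every code path with stable statistics: a few hundred units for spatial
fits (a 500-unit null-calibration fixture), ~10,000 snakebite deaths for
rate-recovery, ~60,000 deaths/year over seven years for seasonality
(matching the national scale of the published daily curve), and 78
literature studies. Poisson solvers use Newton iterations with step halving
and a 1e-8 jitter on covariance diagonals; Nelder-Mead hyperparameter search
stops at 0.05 tolerance on the log scale; all randomness flows from
explicit integer seeds.
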