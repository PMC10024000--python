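# Methods

This note records the models, conventions and numerical choices behind
`aqfusion`, and what the synthetic-data tests do and do not establish about
real monitoring data.

## The imputation model

Each pollutant series is treated univariately on its own sampling grid. The
latent "true" concentration follows a scalar AR(1),

    x_t = A x_{t-1} + B u_t,    y_t = x_t + ε_t,

with `u_t`, `ε_t` independent unit-variance Gaussian white noises. The
measurement variance is fixed at 1 on the raw concentration scale — the
series is *not* standardised first. This is a deliberate literal reading of
the model statement; an optional `prescale` switch (divide by the sample SD
of observed values, back-transform the smoothed output) is provided for
poorly scaled series but is off by default.

`A` and `B` are estimated per series by maximising the Gaussian
prediction-error log-likelihood, with missing observations skipped in the
filter update. Numerical choices:

- optimisation over `(A, log B)` with a Nelder–Mead simplex, start point
  `(1, log 1)`, objective tolerance 1e-6; the log transform enforces
  `B > 0` without an explicit bound;
- `A` is *not* constrained to `|A| < 1`; the optimiser may settle near a
  random walk, which is legitimate for strongly persistent series;
- initial state prior: mean = first non-missing observation, variance =
  10 × the sample variance of observed values (fallback 10 for degenerate
  series). A wide data-driven prior makes early smoothed values data-driven
  without a formal diffuse filter; the dense-conditioning oracle in the
  tests uses the identical prior, so the equivalence check is exact;
- constant series drive `B̂ → 0`; this is reported through the fitted
  parameters and convergence flag rather than raised as an error;
- at least 10 observed values are required to fit.

Bi-hourly series are filtered on their native 2 h grid; they are not
embedded into an hourly grid with deterministic missingness. Observed
entries always keep their observed value in the output; smoothed means
replace missing entries only.

## Daily aggregation and uncertainty

Days are UTC calendar days; partial first/last days are aggregated over the
entries present if they pass the gap rule. "A gap larger than six hours" is
read as a *consecutive* run of originally-missing entries spanning more
than 6 h — not a cumulative count, which would permanently invalidate
bi-hourly series. Runs are measured on the full series, so a gap crossing
midnight counts against every day it touches; this reading keeps the rule
monotone (extending a run can never revalidate a day).

The daily imputation uncertainty is

    σ_d = sqrt( (1/m²) Σ_{t∈d, imputed} Var(x_t | y_1..y_n) ),

with `m` the entries per day (24 hourly, 12 bi-hourly). Two generalisations
of the printed hourly-only form are intentional: the divisor `24²` becomes
`m²` for non-hourly steps, and the sum runs over *imputed* entries only —
the latter is forced by the contract that fully observed days carry exactly
zero uncertainty. The formula assumes the smoother errors of distinct hours
are uncorrelated; in truth neighbouring smoothed states are positively
correlated within a gap, so σ_d understates the variance of long-gap daily
means. The Monte-Carlo test resamples imputed hours independently and
therefore validates the formula under its own assumption, not the
correlated truth.

## Spatial alignment

IDW uses the four nearest cell centres with power 1, distances Euclidean in
degrees (the published operator; a great-circle option exists). The output
is a convex combination, hence bounded by the neighbour values. Ties at the
fourth rank resolve to the smaller (lat, lon) lexicographic order for
determinism; a point exactly on a cell centre returns that cell's value —
the limit of the diverging 1/d weights. "Four nearest by distance" is used
rather than the enclosing 2×2 block; the two differ only near cell-edge
equidistance, where the tie rule decides. No land/sea or domain masking is
applied. The municipal join prefers the declared municipality and falls
back to the nearest centroid (ties again lexicographic), which handles
stations whose own municipality lies outside the covered domain.

## Temporal disaggregation

Monthly values are anchored on the 15th of their month: the anchor day is
not dictated by the data sources, and mid-month minimises phase error for
month-average quantities. Census knots sit at 30 June / 31 December, with
an optional pre-period 31 December value prepended to reduce edge effects.
Interpolation is PCHIP (Fritsch–Carlson derivative limiting, as implemented
by `scipy.interpolate.PchipInterpolator`): it passes through every knot,
preserves local monotonicity and cannot leave the knot range on an
interval, so non-negative counts stay non-negative — the reason classic
cubic splines are avoided. No extrapolation: daily dates outside the knot
span are an error at the interpolation layer, and pipeline callers leave
such trailing days missing (e.g. emissions after the last monthly knot).
The test suite checks the implementation against an independently coded
Fritsch–Carlson derivative formula with its own Hermite evaluator.
Categorical and annual layers are expanded forward-constant by calendar
year, never interpolated, because the classes are nominal; years after the
last available value become missing.

## Derived variables

The Magnus constants (17.625, 243.04) are Celsius-calibrated, so Kelvin
inputs are converted before the humidity formula. RH is computed at the
sub-daily resolution and then aggregated (min/mean/max per day) rather than
from daily temperatures — the three daily RH statistics require it. Wind
direction uses the meteorological "blowing from" convention,
`θ = atan2(−u, −v)`, discretised into eight 45° sectors with N covering
[337.5°, 22.5°); calm winds (zero vector) yield a missing direction rather
than an arbitrary sector. Accumulated reanalysis fields (precipitation,
radiation) are taken as already-per-hour quantities; no de-accumulation of
forecast-step semantics is attempted.

## Assembly and formatting

The output table is the full station × day cross product (S × T rows), 41
columns: 5 header + 7 AQ + 16 WE + 7 EM + 2 LI + 4 LA, ordered
header → AQ → WE → EM → LI → LA. Anomaly handling is an explicit,
user-supplied exclusion list — by design not an automated outlier search.
Values are written in scientific notation with four significant digits,
coordinates in fixed point with nine significant digits, missing cells as
the literal token `NaN`, dates as `YYYY-MM-DD`; re-reading and re-writing a
dataset reproduces it byte-for-byte because the formatter is idempotent on
its own output. Period endpoints are inclusive and leap days are included
(2016 and 2020 in the reference period: 2192 = 366+365+365+365+366+365).

## The synthetic generators

The generators emulate the *structure* the methods assume, not any real
region: hourly/bi-hourly series are latent AR(1) (default coefficient 0.9,
innovation SD 2 µg/m³) plus a sinusoidal 24 h cycle (amplitude 5 µg/m³)
over a baseline of 20 µg/m³, observed with unit-variance noise; missingness
is independent Bernoulli dropout (default rate 0.10) plus geometric-length
bursts (mean 8 h, start rate 0.002 per step) so that runs exceeding six
hours actually occur and exercise the gap rule. Station type frequencies
follow the published land-use × emission-context taxonomy counts;
municipalities are nearest-centroid assignments to a small random centroid
set — enough to test the municipal join without GIS. Gridded fields are
band-limited random surfaces (smooth in space, periodic in time); monthly
fields are built in log space and hence strictly positive, as emission
fluxes must be. Every generator is deterministic given the configuration,
via per-stream seeds derived from the config seed and a stable CRC of the
stream name.

What passing tests show: the pipeline's operators are correct on data
satisfying their stated assumptions, with imputation error measurable
against retained latent truths. What they do not show: performance under
real-world features the generators omit — spatially correlated sensor
dropout, validation-flag politics, heavy-tailed concentration spikes,
instrument drift, or realistic spatial covariance of fields and emissions.

## Problem sizes

The test suite works at deliberately modest sizes chosen to pin down each
property sharply: smoother-vs-dense-conditioning checks at n ≤ 50 (where
O(n³) conditioning is exact and cheap), likelihood parameter recovery at
n = 5000 over 20 replicates, PCHIP guarantees over 1000 random knot sets,
and the full-scale table-shape identity at the reference network size
(141 stations × 2192 days).

## Known limitations

- The univariate model ignores cross-pollutant and cross-station
  information; multivariate or physico-chemical imputation is out of scope.
- σ_d understates long-gap uncertainty (see above).
- `A` near 1 with short series can make the likelihood surface flat;
  convergence flags should be checked when fitting very short series.
- The NetCDF reader goes through xarray and accepts CF-style regular grids
  only; the flat CSV grid dialect is the primary tested path.
- No GIS: municipality membership and land-class assignments are accepted
  as precomputed inputs.
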