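# Methods

This package measures the equity of Traditional Chinese Medicine (TCM)
health-resource allocation across the 31 provinces of mainland China and
forecasts national resource totals over a five-year horizon. Four
indicators are tracked: TCM medical institutions, TCM beds, practitioners
(assistants) of TCM, and Chinese pharmacists. The provinces are grouped
into the four customary economic regions — Northeast (3 provinces),
Eastern (10), Central (6), Western (12); Hong Kong, Macao and Taiwan are
out of scope.

## Concentration index

Provinces are ranked ascending by per-capita GDP (GDP divided by resident
population, derived at use time; ties broken alphabetically for
reproducibility). With X_i the cumulative population share and Y_i the
cumulative resource share (X_0 = Y_0 = 0), the index is the trapezoid form

    CI = 1 − Σ_{i=1..n} (X_i − X_{i−1})(Y_i + Y_{i−1}),

twice the signed area between the concentration curve and the diagonal.
CI ∈ [−1, 1]; CI > 0 means the resource favours richer provinces, CI = 0
proportional allocation. The implementation verifies, when ranking keys
are attached to a `ShareSeries`, that the units really are ordered
poorest-first, and refuses zero-total resources rather than returning an
undefined value. Both a province-level (31 units, the default) and a
region-level (4 units) mode are provided; the region mode is deliberately
coarse and exists for sensitivity checks only.

The index satisfies, and the test suite enforces: zero at proportional
allocation, |CI| ≤ 1, antisymmetry under rank reversal, monotonicity under
poor-to-rich transfers, and invariance to rescaling the resource counts.

## Theil index and decomposition

For weight shares P_i (population, or land area in the geographic variant)
and resource shares Y_i,

    T = Σ_i P_i log(P_i / Y_i),   T ≥ 0,

with zero-weight units contributing zero and a hard error — not epsilon
smoothing — when a positive-weight unit has zero resource, since smoothing
silently changes the index. The logarithm is natural by default and
configurable (base 10 available); contribution rates are base-invariant,
absolute index values are not.

Grouping provinces into regions decomposes T exactly:

    T = T_between + Σ_g P_g T_g,

where T_between is computed on region aggregates and T_g inside region g
on renormalised shares. The total is computed both directly and as
within + between; a discrepancy beyond 1e-9 raises an internal-consistency
error. Contribution rates are 100·within/T and 100·between/T, reported as
not-applicable when T = 0. The geographic variant replaces population
shares with land-area shares, the standard construction in the
agglomeration/Theil literature.

## Agglomeration degrees

A region's health-resource agglomeration degree is its share of the
national resource divided by its share of national land area,

    HRAD_g = (HR_g / HR_n) / (A_g / A_n),

and PAD is the same ratio for population (the ×100% in numerator and
denominator cancels, so plain share ratios are used). HRAD < 1 flags
insufficient geographic provision; HRAD/PAD compares resource density with
population density and algebraically reduces to resource share over
population share, independent of area. Flags use strict inequalities at 1
with exact equality reported as "balanced". Two identities are enforced in
tests: the area-weighted mean of HRAD (and of PAD) over regions is exactly
1, and the ratios are invariant to rescaling all areas.

## GM(1,1) grey forecasting

The national series X⁰(1..n) (n ≥ 4, strictly positive, non-constant) is
accumulated to X¹(k) = Σ_{i≤k} X⁰(i); trapezoid background values
z¹(k) = ½(X¹(k) + X¹(k−1)) form the overdetermined system
X⁰(k) = −a·z¹(k) + u, solved by ordinary least squares for the development
coefficient a and grey action quantity u (a < 0 corresponds to growth).
The background coefficient is fixed at ½ and not exposed as a tunable.
Fitted and forecast values come from the time response

    X̂¹(k+1) = (X⁰(1) − u/a) e^{−ak} + u/a,  k = 0, 1, …

restored by first differencing, with x̂⁰(1) = X⁰(1) by convention (the
first observed year maps to k = 0, so the second year's value uses
e^{−a·1}). Degenerate fits (|a| < 1e-12) are rejected.

A numerical subtlety documented because tests rely on it: a series that
satisfies the *difference* equation exactly is recovered by least squares
with machine-precision (a, u) and exactly consistent difference-form
residuals, but the *restored* values use the continuous exponential, whose
step ratio e^{−a} differs from the recursion's (1 − a/2)/(1 + a/2) by
O(a³) per step; restored residuals therefore carry an O(a²) relative
discretization error (about 1.2e-3 at |a| = 0.1). Tests assert exactness
on the difference form and the O(a²) envelope on the restoration.

### Accuracy test

With population (divide-by-n) dispersions over all n in-sample years
(first residual identically zero): S1 is the dispersion of the data, S2 of
the residuals ε, and the small-error probability is

    P = (1/n) · #{k : |ε(k) − ε̄| < 0.6745·S1},

using standard deviations. The posterior error ratio C is reported, by
default, as the ratio of variances S2²/S1²; the standard-deviation ratio
S2/S1 is available via `accuracy_test(..., convention="std")`. The
variance form is the convention under which the packaged national-series
diagnostics take their published values (C = 0.002 for institutions), and
both conventions grade identically here. Grades follow the conventional
ladder: level 1 if P > 0.95 and C < 0.35, level 2 if P > 0.80 and
C < 0.50, level 3 if P > 0.70 and C < 0.65, level 4 otherwise; level 1
certifies the model for extrapolation.

Each indicator is fitted independently; multivariate or rolling grey
variants, prediction intervals, and model comparison against other
forecasters are out of scope.

## Synthetic panel generator

Because the provincial covariates behind the published equity tables live
in supplementary data not shipped here, the equity half is validated on
synthetic panels whose *structure* matches the real one: 31 provinces in 4
regions over 5 years (both configurable), heavy-tailed population
(lognormal, σ = 0.8 around 30 M) and area (lognormal, σ = 1.0 around
300,000 km²), a regional per-capita GDP gradient with
Eastern > Central > Northeast > Western and a default richest-to-poorest
ratio of 2.5, and national totals starting at the approximate real 2016
scale (50,000 institutions; 1,000,000 beds; 480,000 practitioners;
120,000 pharmacists) growing by e^g per year with g = 0.08 — the order of
the observed 8–9% annual growth of the real series.

Allocation couples to wealth through count_i ∝ pop_i · (pcGDP_i/mean)^γ ·
noise_i: γ = 0 with zero noise gives exactly proportional allocation
(CI = 0 and T = 0 up to integer rounding), γ > 0 concentrates resources in
richer provinces (CI > 0), γ < 0 the reverse. Counts are rounded last with
largest-remainder correction so yearly national totals match their targets
exactly, which keeps aggregation identities exact in integer arithmetic.
A fixed seed yields a byte-identical panel.

What the generator does *not* emulate: spatial autocorrelation, serial
reallocation dynamics (a province's relative endowment is drawn once and
held), calibration to real yearbook marginals, or sub-provincial units.
Passing tests therefore demonstrate the correctness and invariances of the
index computations and the pipeline, not empirical claims about the real
provincial distribution.

## Problem sizes and numerical choices

The default analysis runs 31 × 5 panels and five-point national series;
the whole test suite and the analysis drivers complete in seconds. Share
sums are validated to 1e-9; decomposition identity to 1e-12 in tests;
parameter recovery to 1e-10. Published grey-model quantities are compared
after rounding to their printed 3-decimal precision, with a pre-rounding
guard of half an ulp of that precision for a and 0.05% relative for u and
the forecasts (the printed values are rounded outputs of an unrounded
computation). Forecast horizons are indexed by calendar year and must lie
strictly after the last observed year.

## Known limitations

- The published equity tables (concentration, Theil, agglomeration of the
  real data) are not reproduced numerically, since they require the
  supplementary provincial covariates; the equity half is validated by its
  mathematical properties instead.
- GM(1,1) assumes quasi-exponential growth; it extrapolates a five-point
  series and says nothing about structural breaks.
- The region-level concentration mode uses only 4 units and should not be
  over-interpreted.
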