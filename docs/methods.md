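# Methods

## The index model

The package computes a chained, hierarchically averaged index of
population change.  The atomic quantity is the annual log10 growth rate
`lambda_t = log10(N_t / N_(t-1))`, computed for every population on
gap-free, strictly positive yearly values and assigned to the later year
of each pair.  Lambdas are averaged arithmetically (equivalently: growth
ratios are averaged geometrically) up a fixed hierarchy for each year
separately:

1. populations of one species within one biogeographical realm
   (unweighted) — a species occurring in two realms is deliberately two
   independent units, because the species mean is defined within a realm;
2. species within a taxon-realm cell (unweighted);
3. taxa within a realm — weighted by the share of the realm's species
   richness held by each taxon, when weighting is on;
4. realms within an ecosystem — weighted by realm richness shares;
5. ecosystems into the global value, always in equal thirds.

The index is chained multiplicatively from a baseline year (default
1970, index 1): `I_t = I_(t-1) * 10**lambda_t`.  Years inside the
covered range with no data anywhere carry the index forward unchanged
and are flagged on the result (`carried_forward`); erroring here would
make the choice of end year a hard failure rather than a user decision.

Assumptions worth keeping in mind: the hierarchy treats the supplied
taxon/realm/ecosystem labels as exhaustive and correct; weights are
richness *shares* (each level sums to 1); and a taxon or realm absent in
a year is dropped with the remaining weights renormalised for that year.
The renormalisation choice matters — treating a missing group as
`lambda = 0` would fabricate stability for groups that simply were not
surveyed.

## Zero handling

Growth ratios are undefined at zero abundance, so zeros must be either
replaced or removed before log-transformation:

* `replace_one_percent` (the original rule): if a series contains a zero
  in any year, add `0.01 * mean(non-zero values)` to **every** value of
  that series.  The shift is scale-equivariant, but it converts a
  terminal zero into a drop of roughly two orders of magnitude, so
  datasets whose zeros cluster at series ends acquire a downward bias.
* `remove_and_split` (the corrected rule): delete zero observations and
  split the series at each deletion into independent fragments.
  Fragments with fewer than two records are discarded, since a single
  value yields no growth rate.  Fragment ids are suffixed
  deterministically (`#z1`, `#z2`, ...).

Series consisting entirely of zeros are removed under both policies: a
constant shifted all-zero series would contribute exactly `lambda = 0`
everywhere, i.e. pure fabricated stability.  Splitting happens at every
deleted position, including single interior zeros; runs of consecutive
zeros collapse into one cut.

Record-count (`min_records`, >= 2) and span (`min_span_years`,
inclusive: records in 1974 and 1977 span 4 years) filters run after the
zero policy, on observed — never interpolated — records.

## Smoothing

Series with at least 6 records whose values are not all equal are
smoothed on the natural-log scale with a cubic regression spline
(`patsy` `cr` basis, ordinary least squares) with basis dimension
`round(n_records / 2)`, floored at 3 and capped at the record count;
predictions at every year between the first and last observation are
exponentiated back.  The half-the-record-count rule is the pipeline's
smoothing-parameter convention; the spline family was an open choice and
an unpenalized regression spline was selected because it is exact on
log-linear data (so noise-free exponential growth yields constant
lambdas), reproduces constants, and needs no smoothing-penalty
selection.  A stricter fit criterion — minimum deviance explained — can
be enabled (`gam_deviance_threshold`); by default a fit is accepted
whenever the solve converges and all predictions are finite and
positive, and any failure falls back to the chain method.

Shorter series, constant series and failed fits use the chain method:
log-linear interpolation between consecutive observed records, i.e.
missing years are filled with geometric interpolants of the bracketing
observations.  Observed values always pass through unchanged and neither
method extrapolates outside the observed window.

Outlying growth rates can optionally be clamped to `[-cap, +cap]`
(`lambda_cap`, default off — clamping, not discarding, so a record
outlier still contributes its sign).

## Confidence intervals

100 bootstrap replicates (configurable) resample **species** — each with
all of its populations — within every (ecosystem, realm, taxon) cell,
with replacement, back to the original species count.  Each replicate
rebuilds the hierarchy and re-chains the index; the interval is the
2.5/97.5 percentile per year.  Duplicated species count as distinct
contributors to the taxon mean.  With one species per taxon every
replicate equals the original, so the interval has zero width — the
bootstrap measures between-species variance only.  Replicates reuse the
per-population lambdas (preprocessing and smoothing are deterministic
per series), and the generator is seeded from the run configuration, so
results are bit-reproducible.

## Simulated fluctuation scenarios

Four ensemble scenarios (defaults: 500 populations, 50 years, initial
size 50) characterise when the index is biased:

| scenario | dynamics | expected index |
|---|---|---|
| `stationary_arithmetic` | iid Normal(50, sd=10) per year | flat |
| `stationary_log` | iid lognormal, sd 0.2 on ln scale | flat |
| `poisson_walk` | `N(t+1) = N(t) ± Poisson(3)`, absorbed at 0 | declining |
| `log_walk` | `log10 N(t+1) = log10 N(t) + Normal(0, 0.2)` | flat, drifting mean |

The Gaussian dispersions (sd 10 arithmetic, 0.2 log) are package
defaults chosen to give visible but non-degenerate fluctuation around
the initial size (roughly ±20% per year); they are exposed on
`ScenarioConfig`.  Non-positive draws in the arithmetic scenario are
redrawn (truncation keeps the year-distribution stationary; at the
default sd the truncated mass is ~3e-7, so the effect is negligible).
The Poisson walk records its first zero and truncates there, preserving
the absorbing boundary that makes the scenario non-stationary.

`summarize_ensemble` reports the community mean abundance (absorbed
populations count as 0 — they are extinct, not unobserved), an
equitability proxy (sd of log10 abundance among extant populations; the
true evenness metric of the motivating figures is unstated, so the proxy
is labelled as such), and least-squares slopes of log10 index and log10
mean abundance against year.

The test suite checks, across 20 seeded runs per scenario at the default
500 x 50 size: stationary scenarios give a mean index slope within 3
Monte-Carlo standard errors of zero; the Poisson walk gives a negative
slope in at least 19/20 runs while its mean abundance stays flat; the
log walk keeps a flat index while its mean abundance drifts
significantly upward (the expectation of a lognormal random walk grows
even with zero log-drift).  These sizes keep the whole suite around a
minute of simulation; they are the sizes at which the properties are
asserted.

## Synthetic survey-like data

`synth_lpd` generates datasets with the awkward features of real
compilations: ragged start/end years, irregular sampling, a settable
share of two-record series, zeros planted at the start, middle or end of
series, multi-population species and single-population taxon-realm
cells.  Per-population log10 trends are drawn from a Normal distribution
and recorded in a truth map for recovery tests.  What it does **not**
emulate: observation error that depends on abundance (counts are
lognormal around the trend at every size), correlated dynamics among
populations, taxonomic or geographic sampling bias, and proxy-unit
heterogeneity.  Passing tests on this generator therefore validate the
pipeline's arithmetic and its documented sensitivities, not the
representativeness of any real database.

## Sensitivity diagnostics

* `find_single_representatives` counts, per (taxon, realm) and year, the
  populations whose growth rates actually enter the mean — i.e. after
  the zero policy, filters and smoothing — and reports maximal
  consecutive-year runs carried by at most `max_count` populations
  (default 1; the count is configurable because two or three populations
  can exert almost the same leverage).
* `leave_out` recomputes the index with and without a target and reports
  final difference, final ratio and per-year divergence.  With three
  equally weighted taxa, removing the sole representative of one taxon
  whose lambda is -0.3/yr over 4 years changes the final index by
  exactly `10**(4 * 0.3 / 3)` — the closed form the tests pin down.
* `adjustment_grid` runs the full pipeline over a set of named
  configurations x scopes and reports final values and differences from
  the baseline configuration (positive = the adjustment lessens the
  decline).  Per-cell failures (e.g. an ecosystem with no data) are
  recorded in the grid, not raised.
* `compare_groupings` contrasts unweighted indices under two grouping
  schemes (unweighted, because richness weights are defined for one
  particular grouping).

## Numerical choices and degenerate inputs

* Lambda years: the rate for (y-1, y) belongs to year y; the index at y
  reflects change into y.
* Baseline: lambdas at or before the baseline year are dropped with a
  warning; the index never extends before the baseline.
* Weight validation: 1e-9 tolerance on level sums for constructed
  tables, 1e-6 for user CSV files (with an opt-in auto-normalise).
* Equal-weight tables key taxon weights by realm, so a realm shared by
  two ecosystems receives 1/|union of taxa| per taxon; per-year
  renormalisation makes this equivalent to the unweighted mean within
  each ecosystem.
* Aggregation with a single child is an exact pass-through.
* Missing-value markers in the wide CSV: empty, `NULL`, `NA`; any other
  non-numeric cell raises, naming the population and year.
* All randomness (bootstrap, scenarios, synthetic data) flows through
  `numpy.random.default_rng` seeded from the relevant config, so every
  stochastic result is reproducible bit-for-bit.

## Known limitations

* The smoother is an unpenalized regression spline; implementations
  built on penalized smoothers with the same basis dimension will
  produce slightly different interpolated values for noisy gappy series
  (identical for noise-free log-linear and constant series, which is
  what the invariants pin down).
* The exact "fits well" rule of the original pipeline's GAM check is
  not publicly specified; the default here (convergence +
  finite positive predictions) is deliberately permissive and the
  deviance threshold is exposed rather than guessed.
* Replicating published global index values requires the external
  population database and its richness weight tables, which are not
  redistributable; the package validates mechanisms (zero-placement
  bias, sparse-series bias, single-representative leverage) on synthetic
  data instead.
* The weights CSV keys taxon weights by realm name only; a dataset
  needing different taxon weights for the same realm name in different
  ecosystems must encode them as distinct realm labels.
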