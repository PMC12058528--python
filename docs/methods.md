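# Methods

This note documents the statistical model behind `ulex`, the conventions and
numerical choices the implementation fixes where the method leaves them
open, what the synthetic-data generator does and does not emulate, and the
known limitations of both.

## The estimand

For a birth cohort `b` in grid cell `x` (0.5°), lifetime exposure to one
hazard is the sum of annual exposed-area fractions over the cohort's
lifetime,

```
E(x, b) = Σ_{k=0}^{⌊L⌋−1} f(x, b+k)  +  (L − ⌊L⌋) · f(x, b+⌊L⌋),
```

where `L` is the country's life expectancy at birth for that cohort and the
death year contributes the fraction of the year lived. All people in a cell
count as exposed in a year in which the hazard occurs there, so when
`E(x, b)` exceeds the cell's pre-industrial threshold the cell's entire
birth cohort is tallied as having reached unprecedented lifetime exposure
(ULE). The cohort fraction CF(b, pathway) is the emerged count divided by
the cohort total, computed per ensemble member and summarized across
members (mean as the headline statistic; median, quartiles and range
retained for box-plot-style reporting).

"Unprecedented" is calibrated against a stationary pre-industrial climate:
per cell, each control run contributes `n_boot = 10,000` bootstrap lifetimes
(years drawn iid with replacement, 1960 life expectancy, fractional final
year weighted), pooled across control runs; the ULE threshold is the pooled
sample's 99.99th percentile by the nearest-rank rule (rank `⌈0.9999·n⌉` of
the sorted sample, always a sample element). 99.99% is as deep into the
tail as a pooled sample of 40,000–310,000 supports; the percentile
sensitivity levels off beyond it (tested on integer-valued samples at the
largest pooled size).

## Conventions fixed by this implementation

The method leaves several small conventions open; `ulex` fixes them as
follows (all recorded in each run's `manifest.json`):

- **Emergence comparison is strict**: a cohort emerges iff `E > T`, so
  `E = T` does not emerge. With bootstrap samples on a discrete support the
  threshold is a sample element, and non-strict comparison would count the
  threshold's own atom — roughly tripling the nominal 10⁻⁴ false-emergence
  rate in typical configurations.
- **Year-axis convention**: a person born in year `b` with life expectancy
  `L` fully lives calendar years `b … b+⌊L⌋−1` and the fraction `L−⌊L⌋` of
  year `b+⌊L⌋`. Lifetimes extending past the final analysis year (2113) are
  truncated with a logged warning.
- **GMT smoothing** uses a centred 21-year rolling mean whose window
  shrinks symmetrically near the series edges (half-width
  `min(10, i, n−1−i)`), so the earliest years needed from 1960 onward are
  retained rather than discarded; a series shorter than the window
  collapses to its full mean with a warning.
- **Year mapping**: each target year takes the source year minimizing the
  absolute difference between the run's smoothed warming and the pathway
  level; exact ties resolve to the earliest source year (deterministic, and
  it favours less-warmed analogue years). The mapping's validity is judged
  on the maximum mismatch over target years 1960–2113 only.
- **Pathway interpolation** uses only the two anchor trajectories
  bracketing a target level, with weights set by the anchors' year-2100
  values; an anchor exactly at a target level passes through unchanged.
- **Life expectancy**: 5-year blocks (values for 5-year-olds) are taken as
  representative of block midpoints, linearly interpolated to annual birth
  years, held constant beyond the outermost midpoints, and increased by 5
  years to measure expectancy since birth.
- **Cohort sizes**: 5-year age groups are split as total/5 per single-year
  age (the open-ended 100+ group maps to the single age 100), interpolated
  linearly across table years, and extended to 2113 by linear extrapolation
  from the last two annual values with negatives clamped to zero (logged).
  Shares are taken against the interpolated all-age total, so re-aggregating
  at table years reproduces the source exactly.
- **Population extrapolation** beyond 2100 is the recursive 10-year
  trailing mean (2101 = mean of 2091–2100, previously filled years entering
  subsequent means).
- **Quantile stratification** sorts cells by indicator (ties broken by
  stable cell index — rank-based, hence invariant under monotone
  transforms), accumulates cohort population, and closes bin `i` at the
  first cell whose cumulative population reaches `i/k` of the total; cells
  are never split, so bins are equal only up to the largest single-cell
  cohort share, and a very heavy cell can leave a later bin empty (an error
  if that bin is a compared stratum).
- **Ensemble significance** between strata is a two-sided Welch *t*-test
  across ensemble members at α = 0.05, falling back to an exact two-sided
  Mann-Whitney rank test when either group has zero variance (two identical
  constant groups report "not significant" with a flag).
- **Seeding**: every random stage draws from a child generator derived
  deterministically from the master seed and a (stage, run, country) key,
  so outputs are bit-identical across reruns and independent of execution
  order.

## The synthetic world

`ulex.synthetic` generates complete input worlds with recorded ground
truth. Per cell, annual occurrence is Bernoulli with probability
`p(x, t) = clamp(p0(x) + β(x)·W(t), 0, 1)` — the simplest model in which
event frequency increases with warming while lifetime sums stay analytically
tractable — and an occurrence exposes a fixed fraction `a(x)` of the cell.
Defaults: `p0 ~ U(0.004, 0.02)` (a one-in-50-to-250-year event under the
pre-industrial climate, bracketing the once-per-century baseline typical of
threshold-defined extremes), `β ~ U(0.005, 0.03)` per °C (events a few times
more likely at 3 °C than pre-industrial), `a = 1` (cell-filling events, the
heatwave-like case). Controls are 639 years long by default (the richest
control length the archive structure allows; configurable within 239–639).
Forcing runs share a common quadratic historical anomaly reaching 1.2 °C in
2020 and relax smoothly to a scenario-dependent end-of-century level
(1.9 / 2.9 / 4.3 °C for the low/medium/high scenarios, per-model offset
SD 0.15 °C, interannual noise SD 0.08 °C), which staggers maximum warming
across members and exercises the ensemble-thinning constraint. Demography
uses exponential country growth, fixed within-country age structure, and
fixed lognormal cell weights; the deprivation surface is coupled to GDP per
capita by a Gaussian copula at a configurable Spearman correlation
(−0.7 by default; −1 gives the exact reverse ranking).

Two analytic ground truths accompany the generator:

1. **Idealized truth** (`true_cohort_fraction`): lifetime years are
   independent Bernoulli draws along the *target* pathway; the lifetime sum
   is a scaled Poisson-binomial whose tail beyond the exact stationary
   99.99% quantile is computed by O(n²) convolution. This is the natural
   "what the pathway implies" quantity; it underlies the β = 0 invariant
   (false-emergence probability ≤ 10⁻⁴ per cell) and is cross-checked
   against brute-force simulation.
2. **Mapped truth** (`true_cohort_fraction_mapped`): the exact distribution
   of the *pipeline's* resampled lifetime sums, conditional on the realized
   year mappings. Warming-level resampling can pick the same source year
   for many target years (whenever a pathway is flatter than a run's own
   warming), so the lifetime sum is a weighted Bernoulli sum with integer
   multiplicities; the tail is again an exact convolution. Parameter
   recovery is tested against this truth, because the repetition fattens
   tails enough to shift CF by several Monte-Carlo SDs relative to the
   idealized truth — a real property of warming-level sampling, not an
   implementation artifact. One consequence worth knowing: for early
   cohorts, whose emergence is dominated by this resampling variance rather
   than by warming signal, expected CF can *decrease* with pathway level;
   CF monotonicity in the pathway holds (and is tested) for cohorts beyond
   the emergence onset, where signal dominates.

A residual conservative bias remains even against the mapped truth: with
639-year controls the bootstrap threshold jitters asymmetrically upward on
discrete supports (upward excursions of the realized control rate push the
99.99th percentile to the next atom more easily than downward ones pull it
down), depressing measured CF by roughly one Monte-Carlo SD at the tested
scale. It shrinks with control length and is shared by any finite-control
bootstrap of this design.

What the generator does **not** emulate: spatial autocorrelation of
extremes, dependence between hazards, climate-model bias structure,
within-country demographic heterogeneity, and migration or
mortality-feedback dynamics. Passing tests therefore validate the
statistical machinery — accumulation, thresholding, mapping, aggregation,
stratification — under known marginals, not the realism of any particular
hazard's spatial field.

## Problem sizes and tolerances

The shipped test and acceptance configurations are sized for a laptop-class
single CPU: worlds of 6×6 to 20×20 cells, 2–4 ensemble members, 3 pathways
(1.5/2.5/3.5 °C), 10,000 bootstrap lifetimes per control, and 100-cell
calibration runs with 40,000-sample baselines; the full suite runs in under
a minute. Statistical assertions use 2–3 Monte-Carlo SDs computed from the
exact per-cell emergence probabilities (cells independent in the synthetic
world), type-I-error checks allow ±2% around the nominal 5%, and exact
algebraic identities (conservation, relabeling, oracle equivalence) are
asserted to 10⁻⁶–10⁻¹² relative. Floating-point tie and atom comparisons in
the analytic tails use a 10⁻⁹ guard.

## Limitations

- Adaptation, exposure-reduction measures and non-local impacts are outside
  the model by design; ULE is about event counts over a lifespan, not
  severity or assets.
- Country-level life expectancy and cohort shares are applied uniformly
  within countries; within-country demographic gradients are ignored.
- The deprivation surface is treated as static (representative of the most
  recent cohort) while population weights move across birth years.
- The generic localized-percentile occurrence operator stands in for
  hazard-specific event definitions (heat indices, drought persistence,
  flood routing, yield shortfalls, wind thresholds); pipelines consuming
  real data are expected to ingest pre-computed exposure fractions.
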