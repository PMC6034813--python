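# Methods

This note documents the statistical models implemented in `migscale`,
the tunable parameters and their defaults, the synthetic data the test
suite relies on, and the numerical and design choices made where the
published description leaves the details open.

## Scaling relations

A migration quantity `X` (out-migration, inflow from a size class,
international arrivals, ...) is related to city population `P` by
`X = α·P^β`. Estimation is ordinary least squares of `ln X` on `ln P`
(`scipy.stats.linregress` behind `fit_power_law`), so the intercept is
reported on the natural-log scale, `ln α`. Goodness of fit is the
adjusted R² for one predictor, `1 − (1−R²)(n−1)/(n−2)`.

Zero-valued observations have no logarithm; they are dropped from the fit
and counted in `n_dropped_zeros`. A pseudo-count alternative was rejected:
the packaged coefficients come from plain log-log OLS, and transparency
about dropped cells beats smoothing. Degenerate designs (fewer than three
positive observations, or all populations equal) raise instead of
returning meaningless numbers.

Derived quantities:

- per-capita rate `α·P^(β−1)`, clipped to [0, 1] with a warning — the
  number of leavers has a natural upper limit (the residents), and the
  power law can exceed it under extreme extrapolation;
- rate ratio `(P₁/P₂)^(β−1)`, independent of α;
- regime classification against β = 1 at `z` standard errors (default
  `z = 2`; the packaged tables quote ±1 s.e., and the caller chooses `z`).

## The destination exponent curve β(P)

The destination a migrant picks scales with destination size, with an
exponent depending on origin size. To estimate it without committing to
one "small/large" threshold, the population axis (log₁₀ scale) is tiled
repeatedly by non-overlapping windows:

1. each window's width is drawn uniformly from `width_range` decades;
2. the tiling origin is offset left of the smallest population by a
   uniform fraction of the first width, so any population value is
   equally likely to sit anywhere inside a window;
3. windows without cities are discarded;
4. for each remaining window, flows from all member origins are summed
   per destination and regressed (log-log) on destination population —
   windows with fewer than three positive destinations are skipped;
5. each fitted exponent is assigned to every grid point inside the
   window, and grid points average (unweighted) the exponents of all
   windows covering them; the spread (sd) and coverage count are kept so
   a weighted variant can be assessed later.

Defaults: `width_range = (0.02, 0.15)` decades and 1,000 partitions. With
a mean width of ~0.085 decades, a system spanning ~2.6 decades (a US-like
50 k–20 M range) yields roughly 30 windows per partition, i.e. on the
order of 30,000 interval fits per curve, and individual windows match
plausible groupings such as [270 k, 355 k] (0.12 decades). The grid is 50
log-spaced points. Aggregating flows within a window (rather than
averaging per-origin fits) was chosen because small origins have sparse
rows; aggregation stabilises the per-window regression.

`beta_at` interpolates the curve log-linearly in population and clamps
outside the grid. Curves can also be built directly from
threshold-conditioned fits (`threshold_beta_curve`): each "origin below
T" coefficient is anchored at the geometric midpoint of (P_min, T) and
each "origin above T" at the midpoint of (T, P_max). This is a pragmatic
piecewise reconstruction for simulating with the packaged coefficients;
it reproduces the qualitative shape (sublinear below ~1 M, superlinear
above a few million) but not the full resolution of a data-driven curve.

## The two-step scaling simulator

Migration is modelled as a Markovian two-step decision: whether to move,
then where. Per replicate and per city, the sampled residents are split
by a single categorical draw into city-bound movers (probability
`α·P^(β−1)` from the out-migration fit), countryside-bound movers (a
second sublinear relation) and stayers — the two leaving channels are
treated as competing, mutually exclusive outcomes, which guarantees the
three probabilities sum to one and that leavers can never exceed
residents. City-bound movers are allocated across destinations by a
multinomial draw with probabilities ∝ `P_j^β(P_i)` (the curve above), or,
for the gravity-scaling kernel, those probabilities divided by distance
and renormalized (`π′_ij = C·π_ij/d_ij`). Countryside residents enter
the cities by a binomial draw at the per-capita probability
`p = 0.0322` per year, allocated with a sublinear kernel (β = 0.5971);
international arrivals are allocated superlinearly by region-specific
exponents. No births, deaths or emigration.

Sampling protocol: a fraction of each population (default 20%) is
simulated and counts rescaled by its inverse — binomial thinning keeps
expectations exact while cutting cost — and replicates (default 100) are
aggregated cellwise by median, rounded to integer counts. The RNG seed is
part of the configuration and recorded in the result metadata; results
are bit-reproducible given the seed.

## Gravity, radiation and gravity-scaling

- **Gravity**: `F_ij = a·P_i·P_j / d_ij^b`, symmetric by construction.
  Fitting minimises the mean square error over all ordered off-diagonal
  pairs. For fixed `b` the optimal `a` is a linear least-squares
  closed form, so a grid over `b ∈ [0, 3]` (31 points) seeds a
  Nelder-Mead polish over `(ln a, b)`; the procedure is deterministic
  given the data.
- **Radiation**: the standard parameter-free form
  `F_ij = X_i*·P_i·P_j / [(P_i + s_ij)(P_i + P_j + s_ij)]`, where the
  intervening population `s_ij` is the total population of cities
  strictly closer to `i` than `j` is (origin and destination excluded).
  `s_ij` is computed from the finite set of city points, not from a
  continuous density raster, and countryside population is not included.
  In a finite system the raw destination weights do not sum to one, so
  each row is renormalized to the supplied outflow.
- **Gravity-scaling**: the scaling destination probabilities divided by
  distance and renormalized; step 1 is unchanged. Countryside and
  international channels are identical to the scaling model since those
  origins have no defined distance. The model is generically asymmetric.

Distances are great-circle (haversine, Earth radius 6371.0 km) on
lon/lat coordinates; synthetic planar systems may use Euclidean distance
behind the same contract (a constructor flag). Whether published
inter-city distances were great-circle or road distances is not stated
anywhere authoritative; great-circle is the standard convention for
inter-city work and both are supported. For the distance-dividing models
a floor (default: the smallest positive inter-city distance in the
system) guards against co-located synthetic cities.

## Evaluation

`compare_flows` reports the mean square error over all ordered
off-diagonal pairs (the denominator `n(n−1)` is recorded in the report
metadata, since an MSE is only interpretable with its denominator), the
maximum absolute cell error, and per-city marginal scatters.
`small_city_bias` is the mean signed outflow error (predicted − observed)
over cities at or below a population quantile (default 0.25): a fitted
gravity model, dominated by the large-flow pairs, underestimates
small-city outflow when the true leave law is sublinear, and this
diagnostic makes that bias visible. Real-valued predictions are compared
unrounded against integer observations.

## Synthetic data

`SynthSpec` generates city systems with populations from a truncated
Pareto law (tail exponent 1.0 by default — the classic Zipf rank-size
regime — on 50 k–20 M), coordinates uniform over a US-like lon/lat
extent (or a planar box), and OD matrices around the expected flux of a
chosen kernel with Poisson cells (independent, convenient for fitting
oracles) or per-row multinomial counts (conserves leavers, as the
simulator does). The default system size is 385 cities so test geometry
matches a US-scale system; smaller presets keep unit tests fast.

What the generator does *not* emulate: real geography and clustered
settlement patterns, heteroskedastic push/pull factors beyond size and
distance, temporal dynamics, or measurement error in census counts.
Passing recovery tests therefore demonstrates estimator correctness under
the assumed kernels, not that real migration obeys them.

`recovery_experiment` runs replicated generate-and-refit loops with
per-replicate seeds spawned from a master seed and reports truth, mean
estimate, bias, spread and — where the estimator provides a standard
error (the OLS fits) — empirical coverage of ±2 s.e. intervals. The
gravity fitter reports no standard error, so its coverage column is NaN
and recovery is judged on bias against the replicate spread.

## Problem sizes used in the test suite

Recovery checks run at the scale the estimators are meant for: power-law
coverage uses 200 replicates of 385 points with multiplicative noise
σ = 0.3; β(P) recovery uses 385 cities and 1,000 partitions (flat truth
and a two-regime ramp crossing 1 between 1 M and 5 M); gravity recovery
uses 100-city systems (one zero-residual, 15 Poisson replicates); the
simulator expectation oracle uses a 3-city system with 2,000 replicates
at sampling fraction 1; model comparison uses 60-city systems. The whole
suite completes in well under a minute on a single core.

## Known limitations

- The threshold-anchored β(P) reconstruction from packaged coefficients
  is coarse near the phase transition; prefer a data-driven curve when an
  OD matrix is available.
- Gravity fitting by squared error is dominated by the largest flows;
  no Poisson/negative-binomial likelihood alternative is provided.
- The radiation model here uses city points only; applications with a
  dense rural population in the intervening area will understate
  `s_ij`.
- International migration is destination-only: the data this toolkit
  targets carries no information about the origin of arrivals.
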