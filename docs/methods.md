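# Methods

This note records the modelling assumptions, default parameter choices
and numerical decisions behind `warblerpop`, in the spirit of a model
description a maintainer would want before trusting or changing the
code. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Life cycle and projection step

The model tracks females only, in three stages — dominant (`d`), helper
(`h`), non-helper (`u`) — on a half-year age grid from 0.5 to 15 years
(30 subordinate classes; dominants start at age 1 because a promoted
subordinate of age `a` enters dominance at `a + 0.5`). The top age
class is recursive: survivors of age 15 stay at 15. One census step:

1. **Covariates** are taken from the time-`t` census (pre-survival):
   raw total size `N`, standardised as `(N − mean)/sd` with constants
   stored in the kernel, and the subordinate ratio `r`. This matches a
   projection in which rates indexed `t` apply to counts at `t`.
2. **Survival** of every (st)age class at its logistic rate.
3. **Vacancies** `x = max(0, termax − Σ S_d d)`; the weighted lottery
   assigns per-capita promotion probabilities `g_h`, `g_u` with helper
   weight `e^β`. Each probability is capped at 1 independently; when a
   cap binds the exact-allocation identity is allowed to fail and the
   shortfall is logged. With no surviving claimants the pair is (0, 0).
4. **Ageing** within stage for non-promoted survivors; helpers never
   become non-helpers or vice versa (stage switching, observed rarely
   in the field, is excluded from the model).
5. **Reproduction** from time-`t` counts. Dominant reproduction uses
   the expected helper-presence mixture
   `p(a,r)·R_d(q=1) + (1−p(a,r))·R_d(q=0)` rather than drawing a
   per-territory help status: the projection is an expected-value model
   and the mixture is exact in expectation. Newborns enter at age 0.5,
   as helpers with probability `f(mother's age, N)`.

Densities are continuous expected values; nothing is rounded. The
projection therefore carries environmental stochasticity only — one
observed season's intercept vector is drawn uniformly per step, jointly
across all six channels, with no temporal autocorrelation. Joint
resampling (one season index for every function) preserves the
within-season covariance between vital rates; resampling channels
independently would destroy exactly the covariation the kernel design
exists to keep.

Excluded by construction: males, spatial structure, broods of two,
dominants demoting to subordinate, temporal autocorrelation of
environments, individual quality heterogeneity.

## Lottery likelihood

The fit of `β` treats each subordinate-season as a Bernoulli trial with
success probability `min(1, e^β x / (e^β n_h + n_u))` for helpers and
`min(1, x / (e^β n_h + n_u))` for non-helpers. The `min` caps the
probability at 1 (the only reading under which the quantity is a
probability). The MLE is found by bounded scalar optimisation on
`β ∈ [−10, 10]`; the 95% interval is Wald, from the second central
difference of the negative log-likelihood at the optimum (step 1e-4).
Flat likelihoods (every record capped — "everyone wins") and estimates
at the search boundary raise errors rather than returning numbers.
Records aggregate `x`, `n_h`, `n_u` at the season level, so outcomes
within a season share covariates but are treated as independent trials,
matching the binomial-GLM structure of the estimator.

## Default parameterisation (synthetic calibration)

No fitted parameter tables ship with the package; the synthetic module
defines the study conditions. Slopes (logit scale, fixed):

| function | terms | values | shape produced |
|---|---|---|---|
| `S_d` | a, a², a³ | 0.25, −0.02, −0.001 | flat ≈0.92/half-year to ~9 y, then senescent decline |
| `S_h`, `S_u` | a, N | −0.12, −0.25 | identical for the two tactics; declines with age and density |
| `R_d` | a, a², N, q, q·a, q·a² | 0.5, −0.04, −0.15, 2.0, −0.5, 0.04 | rises then falls with age; helped dominants age-constant and elevated |
| `R_h` | a, a², N | 0.5, −0.04, −0.15 | low co-breeding success |
| `f` | a, N | 0.15, −0.1 | recruitment as helper increases with mother's age |
| `p_help` | a, a², r | 0.4, −0.02, 0.5 | peak at exactly 10 y (−b₁/2b₂); increasing in r |

The `q` interactions cancel the age terms of `R_d`, so helped-dominant
reproduction is constant in age. The helper-presence probability is the
one non-seasonal function (single fixed intercept, −1.5). Mother's
status does not enter `f` (its signature is age and density only).

Among-season intercept means/sds: `S_d` 2.2/0.35, `S_h` = `S_u`
2.6/0.12 (correlation 0.9 — one biological survival process, two
perturbation channels), `R_d` −3.8/0.5, `R_h` −4.0/0.2, `f` 0.3/0.15;
other cross-channel correlations zero. Standardisation constants
(170, 20); capacity `termax = 111.2` territories; lottery contrast
`β = −0.549`. These values were chosen once to put the model on the
published scale of the study system — half-year adult survival near
0.92 (annual ≈ 0.84), dominants at capacity, roughly 50 helpers and 12
non-helpers with subordinate totals fluctuating on the order of 20–90,
and a seasonal variance budget dominated by dominant reproduction, then
dominant survival. The generator emulates among-season variation and
within-season covariance of fitted intercepts and individual lottery
records with realistic pool sizes; it does **not** emulate observation
error, imputation uncertainty, pedigree structure, or spatial
neighbourhoods — so passing tests demonstrate correctness of the
machinery under known truth, not fidelity to any particular field
dataset.

## Fitness descriptors

**Cohort LRS.** Each replicate spins up its own resident population
(the cohort "sees" that population's density and vacancies but does not
add to them), then follows a unit cohort recruited at age 0.5 in one
stage, accumulating expected offspring per original member — including
offspring produced after promotion to dominance — until survivorship
falls below 1e-10 (hard cap 2,000 steps, logged). Cohort and resident
share seasonal draws within a replicate; replicates draw fresh
sequences. Across-replicate variation is purely environmental, which is
why cohort LRS contains no zeros.

**Markov chains with rewards.** The transient matrix `U` is the
realized projection matrix of a frozen environment (deterministic fixed
point under fixed intercepts) with the reproduction rows removed;
rewards are per-step Bernoulli reproduction probabilities, so all raw
reward moments equal the probability and the moment recursions collapse
to three linear solves (first three moments, then CV and skewness).
Chains with spectral radius ≥ 1 are rejected as immortal. In a frozen
environment the cohort simulation and the chain mean are the same
linear recursion, and the tests verify they agree; the chain adds what
the cohort computation cannot: individual-level (demographic)
variance, including the zero mode.

**Reproductive values** are defined as the dominant left eigenvector of
the mean realized projection matrix over the post-burn-in ensemble
(matrices rebuilt at a subsample of stored censuses, default 300),
normalised to 1 at the youngest dominant class, with interquartile
bands from bootstrap resamples of the step-wise matrices. A forward
"marked-lineage" projection (power method on the frozen matrix) is the
cross-check oracle in the tests.

## Perturbation analyses

**LTRE (random design).** Per post-burn-in step, the drawn intercept
vector is paired with the next-step total population size; a random
forest (500 trees, default split rules, out-of-bag R² reported as
variance explained) attributes response variance to the six channels,
importances normalised to percentages. A linearised cross-check
computes common-random-number finite-difference sensitivities of N̂ to
each channel's mean (step `ε^{1/3}·σ_c`, with machine precision `ε`)
and to its sd, and attributes `(sensitivity·σ_c)²` shares. Channels
with no among-season variance contribute zero; a kernel with no varying
channel at all is an error. The per-step response captures step-level
environmental effects; a coarser 20-step block-mean variant sits behind
`response="per_block"`.

**Elasticity** is `[log N̂(x(1+δ)) − log N̂(x)] / log(1+δ)` with
δ = 0.01 by default, from paired simulations sharing one seasonal draw
sequence (common random numbers; the pairing demonstrably reduces
variance versus independent runs). Perturbable channels: the six
seasonal intercept vectors (scaled multiplicatively on the logit
scale), the fixed help-probability intercept, and the helper-presence
contrast `q` of `R_d`. Because logit intercepts can be negative, a
literal log-log derivative is ill-defined; the multiplicative contract
on the stored value is the definition used, and the sign of an
elasticity therefore follows the sign of the parameter being scaled
(scaling a negative intercept upward lowers the rate). Readers
comparing channels should compare magnitudes, or perturb on the odds
scale themselves.

## Individual-based model

Discrete birds with the same rate functions: Bernoulli survival,
integer vacancies (capacity rounded to the nearest whole territory —
111 when the projection uses 111.2 — a documented divergence, since
discrete birds cannot fill a fifth of a territory), sequential weighted
sampling without replacement for the lottery (exponential-race
implementation; ties broken by the draws), Bernoulli reproduction with
drawn helper-presence status, stochastic recruitment of newborns.
Reproduction uses the time-`t` census, so a bird can leave an offspring
in the season it dies, exactly as in the projection. Sequential
sampling without replacement differs from the projection's
with-replacement expectation at order 1/pool-size; the consistency
tests use pools of a few hundred birds, where the discrepancy is well
inside Monte-Carlo error. Posterior-predictive-style checks simulate
artificial datasets from a set of parameter draws (one kernel per
draw), mask 10% of observation rows by default (mimicking seasons
without behavioural data; rows, not individuals, are masked), and
report density summaries with predictive quantiles for supplied
reference metrics.

## Numerical choices and problem sizes

- Probabilities via `scipy.special.expit`; intercepts of ±800 underflow
  cleanly to exact 0/1, which the degenerate-case tests exploit.
- Simulations are reproducible from a single integer seed
  (`numpy.random.default_rng`); common-random-number pairs share the
  seed, and the season-draw sequence depends only on the season count.
- Extinction (total density below 1e-6) truncates a run with a logged
  time rather than propagating NaNs; negative or non-finite densities
  raise immediately, naming the stage.
- The default production run is 10,000 steps with a 7,000-step burn-in.
  The test suite and example scripts use shorter horizons (hundreds to
  a few thousand steps) and smaller replicate counts, chosen so the
  full suite completes in a few minutes while every check retains its
  statistical resolution; `scripts/acceptance.py` states its sizes in
  its output (`n` per quantity).

## Known limitations

- The acceptance-grade comparison against the published headline
  numbers requires the study's fitted vital-rate tables, which are not
  redistributed here; the corresponding test documents the expected CSV
  layout and fails with an explanation when the tables are absent.
- The lottery fit treats within-season outcomes as independent;
  overdispersion from shared seasonal shocks is not modelled.
- Reproductive values use the mean-matrix approximation at
  quasi-equilibrium rather than a fully stochastic backward iteration.
- The IBM masks observation rows at random; structured missingness
  (whole seasons unobserved) is not emulated.
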