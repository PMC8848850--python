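# Methods

This note documents the statistical model behind `lifegap`, the
defaults and why they were chosen, what the synthetic data emulate (and
what they do not), and the package's numerical conventions.

## The estimand

For each income group g (five median-relative groups of net equivalised
income) and sex, the package produces a *period* life table: the
mortality experience a synthetic cohort would face if the group's
age-specific death probabilities of the analysis period applied over a
whole life.  From it come life expectancy at birth e0, remaining life
expectancy at 65 e65, the survivor function l_x, and premature
mortality P(death before 65) = 1 − l_65.  Gaps are reported as
G5 − G1 for life expectancies and G1 − G5 for premature mortality, so a
positive gap always means disadvantage for the poorest group.

These are *period*, not cohort, quantities, and the group label is a
current-income state, not a lifetime trajectory: a person contributes
episodes to different groups as their income moves.

## Relative risks: effect-coded proportional hazards

Episodes are one-year person-intervals on the attained-age scale,
`[age, age+1)`, with delayed entry at the age of the first observed
wave; death marks the final episode of a deceased person.  Using age as
analysis time (rather than time-on-study) means the baseline hazard
absorbs the age-mortality relationship non-parametrically — no
functional form for age is imposed — and left truncation is handled by
the counting-process risk sets (at risk at age t iff start < t ≤ stop).

Income group is the sole covariate.  Models are fitted separately per
sex × age band (episode start ≤ 50 vs ≥ 51), because a single lifetime
income effect is implausible while sparse death counts prevent finer
age resolution.  After maximizing the partial likelihood in reference
coding, coefficients are re-centred to the episode-weighted sum-to-zero
(effect) coding,

    log HR_g = β_g − Σ_h w_h β_h / Σ_h w_h ,

with w_h the episode counts, so exp(log HR_g) is relative to the
population-average hazard of the stratum.  Contrasts (e.g. the G1/G5
ratio) are invariant to the centring.  Standard errors of the centred
coefficients come from the corresponding contrast of the inverse
observed information.

Numerical details: the solver exploits that the covariate is
categorical — at each distinct event age only per-group at-risk and
death weights matter — so a Newton iteration costs O(deaths × groups)
regardless of episode count.  Tied event ages (ubiquitous, since
episodes end at integer ages) use the Efron correction by default;
Breslow is a config option.  Convergence is declared when the gradient
max-norm falls below 1e-9 × total death weight; a group with zero
events in a stratum is reported as *undefined* (NaN) and excluded from
the likelihood rather than silently dropped.  Unweighted effect coding
and case weights are config hooks; both default off.

## Life tables and old-age extrapolation

Abbreviated official-style tables provide sex-specific one-year death
probabilities q_x for ages 0–90 per calendar year.  For a multi-year
window the baseline is the unweighted mean of the yearly q_x per age
and sex (pooling on the probability scale, then building one table —
the pooled-period convention).

Because e0 requires a closed table, the hazard m_x = −ln(1 − q_x) is
extrapolated: a least-squares line through log m_x over ages 75–90
(Gompertz) extended to age 111, q_112 = 1 exactly.  The Gompertz form
was chosen for parsimony; the fit window is configurable and a Kannisto
logistic hazard (which plateaus at very old ages, where Gompertz can
overstate mortality) is available.  A fitted *declining* old-age hazard
triggers a warning and a constant-hazard fallback.  The
`validate_extrapolation` helper quantifies the induced error against a
reference table; on the synthetic tables the e0 deviation is below
0.001 years, far inside the 0.05-year tolerance used as the acceptance
bar.

Life-table arithmetic uses single-year ages, separation factor
a_x = 0.5 at all ages (configurable; no infant-mortality refinement by
default since the synthetic tables have no infant hump), l_0 = 1, and
L_x = l_{x+1} + a_x (l_x − l_{x+1}).

## From relative risks to group tables

Fitted ratios transfer to the baseline on the hazard scale,

    q'_x = 1 − (1 − q_x)^HR ,

which is the exact survival-probability transform under proportional
hazards and cannot push q above 1 (direct multiplication of q could).
The HR switches at the 50/51 boundary with no smoothing, mirroring the
estimation bands; the closure probability q_112 = 1 is preserved.  Note
an intentional asymmetry: the baseline table represents the population
average on the *log*-hazard scale (the effect-coding convention), while
an actual population mixes survivor curves on the probability scale.
The `mixture_consistency` helper measures the resulting aggregation
gap; for realistic ratio spreads it is well under half a year of e0.

Delta-method standard errors for group metrics and for G5−G1 gaps are
provided (`metric_standard_error`, `gap_standard_error`): they
propagate only the sampling covariance of the fitted log hazard ratios,
treating the baseline table as fixed — the same convention the method
itself uses.

## Trends

The full estimation is repeated per calendar window: pooled baseline
from the window's yearly tables, relative risks re-fitted on the
window's episodes.  The default scheme is overlapping 9-year windows
stepped by one year — sub-period estimates are noisy (few deaths per
stratum), so wide windows are the safer default; non-overlapping and
explicit window lists are supported.  Income groups keep the
full-period pooled median by default (a single threshold set across
windows); a per-window median is a config option.  A window in which
some group has no deaths is flagged and skipped, not fatal.  No
statistical test for gap widening is offered: sub-period estimator
noise makes such a test unreliable at panel scale, and quantifying
that is outside the package's scope.

## The synthetic data

`synthdata` emulates the structure the method assumes, at the scale of
the motivating study (defaults: 83,287 persons, annual waves
1992–2016, ~5% deaths, ~7.4 observed years per person):

* **Mortality**: Gompertz–Makeham hazard h(x) = c + a·e^{bx} with
  a = 7.922e-6, b = 0.11, c = 2e-4 for women and a male log-excess of
  0.5956 — solved once so the reference-year tables give e0 = 80.8
  (women) and 75.0 (men); c matches realistic young-adult death rates
  (q_30 ≈ 4e-4 for women).  A sex-neutral secular improvement of the
  log hazard (0.016/year, anchored mid-period) produces e0 gains of
  roughly +3.7 years over 25 years.  With only three hazard parameters
  per sex, e65 comes out somewhat high (≈18.9/14.7 years) relative to
  real tables with the same e0 — matching e0, e65 and young-age rates
  simultaneously is overdetermined, and e0 plus young-age realism took
  priority because the ≤50 estimation band needs deaths.
* **Group effects**: true log hazard ratios per sex × age band follow a
  monotone profile across groups scaled to G1/G5 ratios of 2.2/2.4
  (women/men ≤ 50) and 1.5/1.9 (51+), centred to share-weighted mean
  zero, where shares are the analytic lognormal group shares — so the
  generating convention matches the estimator's effect coding.
* **Income**: log equivalised income is a stationary AR(1)
  (persistence 0.92) with lognormal marginal, median €1,495 and
  σ = 0.45; group membership is therefore time-varying.  Household
  composition (adult count, children) is drawn per person; the panel
  stores household income = equivalised income × OECD divisor, so the
  income module reconstructs the intended distribution exactly.
* **Observation process**: staggered entry (uniform over the window),
  entry ages Beta(1.0, 2.45)-shaped on [17, 90] (mean ≈ 37), geometric
  attrition at 0.075/year — together yielding ~4.7% deaths and ~7.4
  observed waves per person.  Attrition is independent of future
  mortality (non-informative censoring); a config switch makes it
  depend on the current hazard multiplier to emulate health-selective
  drop-out.
* **Reproducibility**: each person owns a Philox stream spawned from
  the global seed; output is byte-identical across runs and
  independent of iteration order.  Death times use exact inverse-
  transform sampling of the cumulative hazard, piecewise per one-year
  episode so time-varying group membership is honoured; the exact
  fractional death age is stored as ground truth (`death_age`), which
  real panels do not observe — episode construction ignores it by
  default.

What the generator does **not** emulate: survey weights, imputation
and refreshment samples, infant/accident humps in the age profile of
mortality, sex-specific improvement rates, income measurement error,
and any correlation between income and age beyond stationarity.
Passing tests therefore demonstrate that the *pipeline* recovers known
structure from data of this shape and scale — not that any particular
real-world gap estimate is correct.

## Problem sizes used in checks

The test suite and the reproduction script run at desk scale as the
package's own choice of simulation size: unit and property tests use
panels of 6,000–40,000 persons (160,000 for the crude-rate recovery
property, which stipulates ≥50,000 episodes per group), the
confidence-interval coverage property uses 800 replicates of a
two-group design, and `scripts/acceptance.py` simulates 40,000
persons.  At panel scales like these, the ≤50 age band carries only a
few hundred deaths — exactly why the method uses two broad age bands —
so ratio estimates in that band have log-scale standard errors around
0.2; gap and recovery checks are therefore stated in units of their
propagated standard errors wherever a fixed tolerance would be
noise-dominated.

## Known limitations

* The hazard-power transform assumes the fitted ratios apply uniformly
  within each age band; any real age-dependence inside a band is
  flattened, and the 50/51 discontinuity is not smoothed.
* The baseline-as-fixed convention understates total uncertainty in
  group life expectancies (official tables carry their own, small,
  sampling error).
* Effect-coded ratios are relative to the *panel's* average, which
  equals the national average only insofar as the panel is
  representative; no survey weights are applied by default.
* Period life expectancy under secular improvement understates the
  lifespan of real cohorts; all outputs are period quantities.
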