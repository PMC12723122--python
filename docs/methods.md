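# Methods

## The accrual model

Enrollment is modelled as a Poisson counting process on seasonal quarters.
For quarter *j* with exposure *t_j* (fraction of a full quarter) and season
*S(j)*, the count is

- homogeneous model: m_j ~ Poisson(λ t_j),
- seasonal model:    m_j ~ Poisson(λ_{S(j)} t_j),

with conjugate Gamma(α, β) priors on λ (or independently and identically on
each λ_s).  **β is a rate parameter** (density ∝ λ^{α−1} e^{−βλ}); some of
the accrual literature calls the same quantity a "scale", but every formula
in this package and all results it reproduces use the rate reading, under
which β has units of quarters of exposure and α of participants.

Posteriors are exact: Gamma(α + Σ m_j, β + Σ t_j), per season in the
seasonal model.  Because the posterior is in closed form, all sampling here
is direct i.i.d. gamma/Poisson simulation.  MCMC would be distributionally
identical after convergence but strictly worse (correlated draws, burn-in,
tuning); burn-in is therefore not a concept in this package.

### Assumptions

- Counts in disjoint quarters are conditionally independent given rates.
- The seasonal model's four rates are a priori independent — no smoothing
  toward each other (no hierarchical pooling) and no trend within a season.
- Exposure enters linearly: half a quarter at rate λ expects λ/2 arrivals.
- No per-center structure: rates are trial-level aggregates.

## Parameters and defaults

| parameter | meaning | units | default |
|---|---|---|---|
| α, β | gamma prior | participants; quarters | elicited |
| p (`confidence_p`) | prior weight: pseudo-exposure in quarters | — | 0.5 |
| R (`replicates_R`, `draws`) | Monte-Carlo replicates | — | 10,000 |
| `level` | credible/predictive interval mass | — | 0.95 |
| `partial_threshold` | first-quarter coverage below which it is dropped | fraction | 0.5 |
| `seed` | master RNG seed | — | 20180625 |

Elicitation sets α = (planned N / planned quarters) × p and β = p, so the
prior mean always equals the planned rate and p alone controls its weight;
β = p is exactly p quarters of prior exposure, which is why the constant 1
appears multiplying p in the β formula.  Elicited shapes are returned
unrounded; analyses that published rounded hyperparameters can be matched
exactly by passing an explicit `GammaRatePrior`.

## Calendar conventions

Seasons are meteorological with mid-month boundaries.  The boundary day is
the 16th of March/June/September/December: the 15th belongs to the ending
season, the 16th to the starting one.  The choice of day within "mid-month"
is a genuinely open convention; the 16th splits each boundary month as
evenly as possible and makes a trial starting June 25 unambiguously a
summer start.  A calendar month is assigned to the quarter containing its
16th day, so summer = {Jun, Jul, Aug} for monthly aggregation.  Custom
calendars (e.g. southern hemisphere) are supported via `SeasonCalendar`.

Partial first quarters: the day-exact first-quarter exposure is
(days from trial start to the quarter boundary)/(days in the quarter).  By
default the starting quarter is nevertheless recorded with t = 1
(`full_first_quarter`), which matches how the motivating analyses treated a
late-June start; the day-exact mode is a flag away.  With
`drop_partial_first`, a first quarter covering less than
`partial_threshold` of its span is excluded from the likelihood and its
count reported separately (`excluded_count`) — excluded participants still
count toward observed totals in predictions, since they are real
enrollments.  A trailing quarter with fewer than three recorded months gets
exposure months/3; monthly counts cannot resolve days, and the spec-level
constraint (interior quarters have t = 1) is unaffected.

## Predictive simulation: the shared-draw scheme

Per replicate, **one** rate draw per model parameter is shared across all
of that replicate's future quarters (per season in the seasonal model),
then each future quarter gets an independent Poisson count.  For the
homogeneous model this gives

    Var(total) = (Σ t_j)·μ + (Σ t_j)²·σ²,

with μ, σ² the posterior mean and variance.  The alternative — redrawing
the rate for every quarter — averages rate uncertainty away across the
horizon and produces intervals that are too narrow; the published interval
widths this package reproduces are only consistent with the shared-draw
variance.  The per-quarter mode is available (`per_quarter_draws=True`)
for sensitivity analysis.  Predictive totals are bounded below by the
observed total by construction.

## Seasonal comparison

All comparison probabilities for one posterior are computed from a single
shared 4×R matrix of joint draws, so P(λ_s>λ_k) + P(λ_k>λ_s) = 1 and
prob_max(s) ≤ min_k P(λ_s>λ_k) hold exactly on the sample.  Floating-point
ties count as "not strictly greater" (they have probability zero in exact
arithmetic).  The pairwise probability also has the exact form
P(λ_s>λ_k) = 1 − I_{b_s/(b_s+b_k)}(a_s, a_k), derived from
B = b_s λ_s/(b_s λ_s + b_k λ_k) ~ Beta(a_s, a_k); the identity is verified
in the test suite against a quadrature oracle over a grid of small-shape
gamma pairs before being trusted anywhere.

## DIC and rolling evaluation

Deviance is −2 × Poisson log-likelihood *including* log(m_j!), so absolute
DIC values are comparable with BUGS-family output; the constant cancels in
model differences regardless.  The plug-in point for pD = D̄ − D(θ̄) is the
posterior mean of the rate(s) — the classic choice and the default in the
BUGS lineage; the originating analyses did not state their plug-in.  With
abundant data pD ≈ 1 for the homogeneous model and ≈ 4 for the seasonal
model, which the tests confirm on large synthetic series.

Rolling internal prediction treats quarters 1..k as observed (k = 1..J),
refits, simulates R totals for the remainder with the shared-draw scheme,
and scores against the realized total M_true = Σ_{j≤J} m_j (the realized
total, not the planned target):

    RMSE² = Bias² + SD²·(R−1)/R   (identically, on the same draws).

Each k draws from an independent child stream of the master seed
(`SeedSequence.spawn`), so per-k results are independent yet reproducible.
At small k some seasons are unobserved; their predictions use the
unmodified prior, which is the honest interim-monitoring behaviour.
At k = J all three metrics are exactly zero.

## Synthetic data

The generator forward-simulates the seasonal model itself: cyclic season
labels from a start season, unit exposures unless specified, Poisson counts
at the true rates.  `rate_dispersion` optionally multiplies each quarter's
mean by a gamma variable with mean 1 and that variance, producing
negative-binomial-like over-dispersion for robustness experiments.  Two
presets bracket realistic regimes: `hobit-like` (rates 7.2/6.4/4.3/5.1 per
quarter — a slow trauma trial) and `boost3-like` (45.7/37.4/35.5/31.1 — a
fast one), taken from the published seasonal estimates of the motivating
trials.

What the generator does *not* emulate: center openings and closings,
secular trends, enrollment caps, screening funnels, or dropout.  Passing
recovery and coverage tests therefore shows the inference is correct *under
the model*, not that real accrual is Poisson-seasonal; the rolling
evaluation on real data is the tool for that question.

## Problem sizes and numerical notes

Defaults mirror the published analyses: R = 10,000 replicates/draws and
95% intervals.  Validation experiments in the test suite use 100–500
replications with series of 8–40 quarters, and property checks of
Monte-Carlo laws use up to 10⁶ draws; simulation-heavy property tests run
the rolling evaluation at R = 1,000–2,000 since the identities they check
are R-independent.  Empirical quantiles use numpy's default (linear
interpolation) definition.  Posterior intervals are equal-tailed, not HPD.
Degenerate inputs are contracts, not surprises: empty series return the
prior, a zero-quarter prediction returns the observed total with a
degenerate interval, and SD requires R ≥ 2.

## Known limitations

- Four free rates and no pooling: with very few quarters per season the
  seasonal model is prior-dominated, and DIC's penalty makes the
  homogeneous model win on truly non-seasonal data (by design).
- Season boundaries are fixed a priori; the model cannot discover a phase
  shift in seasonality.
- The reconstruction of per-season totals for the motivating trials (used
  in tests) is exact for every conjugate quantity but is still a derived
  fixture: per-quarter published data do not exist, so absolute DIC values
  and per-k accuracy curves from the original analyses are not
  reproducible and are not claimed.
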