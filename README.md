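# accrualcast

Bayesian prediction of participant accrual in clinical trials, with
season-specific enrollment rates.

Slow accrual is one of the most common reasons trials run over budget, lose
power, or terminate early, and enrollment in emergency-medicine and trauma
trials fluctuates strongly with the season.  `accrualcast` is for trial
statisticians and coordinating centers who monitor enrollment at interim
time points and need a calibrated forecast of total accrual — either under
the classic constant-rate assumption or with explicit seasonal structure.

## Model

Time is measured in *seasonal quarters*: three-month meteorological
intervals (summer = mid-June to mid-September, and so on, with boundaries
on the 16th of the month).  Quarter *j* has an enrollment count *m_j*,
an exposure *t_j* ∈ (0, 1] (fraction of a full quarter), and a season
label *S(j)*.

**Homogeneous model.**  m_j ~ Poisson(λ·t_j) with a conjugate gamma prior
λ ~ Gamma(α, β) (β is a *rate* parameter: density ∝ λ^{α−1} e^{−βλ}).
The posterior is exact:

    λ | data ~ Gamma(α + Σ_j m_j,  β + Σ_j t_j).

**Seasonal model.**  m_j ~ Poisson(λ_{S(j)}·t_j) with independent
Gamma(α, β) priors on each of the four seasonal rates; each season is
updated by the same conjugate formula over its own quarters.

**Prior elicitation.**  From a planned enrollment of N participants over Q
quarters and a confidence weight p ∈ (0, 1]: α = (N/Q)·p, β = p.  The prior
mean is the planned rate N/Q and the prior is worth p quarters of data.

**Prediction.**  The posterior predictive distribution of total accrual
after q quarters is simulated: per replicate, draw one rate per model
parameter from its posterior, draw Poisson counts for every remaining
quarter, and add the observed total; repeat R times (default 10,000).
Sharing one rate draw across a replicate's future quarters propagates rate
uncertainty into the horizon total.

The package also computes pairwise posterior probabilities P(λ_s > λ_k)
(exactly, via a regularized-incomplete-beta identity, or by Monte Carlo),
the probability each season has the highest/lowest rate, DIC for
homogeneous-vs-seasonal comparison, and a rolling internal-prediction
evaluation (refit on the first k quarters, predict the rest, score
RMSE/Bias/SD against the realized total, for k = 1..J).  A synthetic-data
module simulates seasonal accrual with known rates for validation.

## Worked example

```python
from accrualcast import *

prior = elicit_prior(target_enrollment=200, planned_quarters=16, confidence_p=0.5)
series = generate_series(preset("hobit-like", n_quarters=26, seed=123))
post = update_homogeneous(prior, series)
sp = update_seasonal(prior, series)
req = PredictiveRequest.continue_series(series, horizon_q=36, replicates_R=10_000, seed=7)
summ = summarize_predictive(predict_total_seasonal(sp, req))
comp = compare_seasons(sp, draws=10_000, seed=7)
```

This elicits the prior Gamma(6.25, 0.5) — planned rate 12.5/quarter,
half a quarter's worth of confidence — simulates 26 quarters of
slow seasonal accrual (141 participants), and prints:

```
homogeneous rate: 5.56  95% CrI (4.70, 6.49)
  summer  7.23  (5.44, 9.28)
  fall    6.97  (5.21, 8.98)
  winter  4.65  (3.15, 6.45)
  spring  4.50  (3.02, 6.27)
predicted total after 36 quarters: 196.9  95% PI [181, 215]
P(summer is fastest) = 0.573
P(winter is slowest) = 0.444
```

The homogeneous posterior pools everything into one rate (5.56/quarter);
the seasonal posteriors separate the fast summer/fall quarters from the
slow winter/spring ones, and the predictive interval says the trial ends
somewhere between 181 and 215 participants after 36 quarters.  The extreme
probabilities quantify how sure the model is about seasonal ordering —
here 26 quarters of low counts leave real uncertainty.

The same analyses are available from the shell:

```bash
accrualcast simulate --preset hobit-like --n-quarters 26 --seed 123 --out accrual.csv
accrualcast fit accrual.csv --target-enrollment 200 --planned-quarters 16
accrualcast predict accrual.csv --horizon 36 --target-enrollment 200 --planned-quarters 16
```

Each subcommand writes a JSON record echoing the resolved configuration
and seed, so every run is exactly reproducible.

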