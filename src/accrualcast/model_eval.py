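"""Model fit (DIC) and rolling internal-prediction accuracy (RMSE/Bias/SD).

DIC uses the classic decomposition DIC = D̄ + pD with pD = D̄ − D(θ̄): D̄ is
the posterior mean deviance and D(θ̄) the deviance at the posterior mean
rate(s).  Deviance is −2 × Poisson log-likelihood including the log(m_j!)
normalization, so absolute values are comparable with BUGS-style output.

The rolling evaluation treats the first k quarters as observed (k = 1..J),
fits the chosen model on them, simulates R horizon totals for the remaining
quarters with the predictive module, and scores the totals against the
actual full-series total M_true:

    RMSE  = sqrt( mean_r (M̂_r − M_true)² )
    Bias  = mean_r (M̂_r − M_true)
    SD    = sqrt( Σ_r (M̂_r − M̄)² / (R − 1) )

which satisfy RMSE² = Bias² + SD²·(R−1)/R identically on the same draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .accrual_data import SEASON_CYCLE, AccrualSeries, Season
from .conjugate import (
    DEFAULT_DRAWS,
    DEFAULT_SEED,
    GammaRatePosterior,
    GammaRatePrior,
    SeasonalPosterior,
    update_homogeneous,
    update_seasonal,
)
from .predictive import (
    PredictiveRequest,
    predict_total_homogeneous,
    predict_total_seasonal,
)

__all__ = [
    "DicResult",
    "EvaluationResult",
    "deviance",
    "compute_dic",
    "rolling_evaluation",
]

ModelTag = Literal["homogeneous", "seasonal"]


@dataclass(frozen=True)
class DicResult:
    dbar: float
    d_at_mean: float
    p_d: float
    dic: float
    model_tag: ModelTag


@dataclass(frozen=True)
class EvaluationResult:
    k: int
    rmse: float
    bias: float
    sd: float
    model_tag: ModelTag
    replicates_R: int
    m_true: int


def deviance(series: AccrualSeries, rates: float | Mapping[Season, float]) -> float:
    """−2 Σ_j log PoissonPMF(m_j; rate_for(S(j))·t_j), with log(m_j!) included."""
    m = np.asarray(series.counts, dtype=float)
    t = np.asarray(series.durations, dtype=float)
    if isinstance(rates, Mapping):
        lam = np.array([float(rates[s]) for s in series.seasons])
    else:
        lam = np.full(series.J, float(rates))
    if np.any(lam <= 0):
        raise ValueError("rates must be strictly positive")
    return float(-2.0 * stats.poisson.logpmf(m, lam * t).sum())


def _deviance_over_draws(series: AccrualSeries, lam_matrix: np.ndarray) -> np.ndarray:
    """Deviance for each row of per-quarter rate draws (R x J)."""
    m = np.asarray(series.counts, dtype=float)[np.newaxis, :]
    t = np.asarray(series.durations, dtype=float)[np.newaxis, :]
    return -2.0 * stats.poisson.logpmf(m, lam_matrix * t).sum(axis=1)


def compute_dic(
    series: AccrualSeries,
    posterior: GammaRatePosterior | SeasonalPosterior,
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> DicResult:
    """DIC with the posterior-mean plug-in (pD = D̄ − D(posterior mean))."""
    rng = np.random.default_rng(seed)
    J = series.J
    if isinstance(posterior, SeasonalPosterior):
        season_idx = np.array([SEASON_CYCLE.index(s) for s in series.seasons])
        per_season = np.empty((draws, 4))
        for i, s in enumerate(SEASON_CYCLE):
            post = posterior[s]
            per_season[:, i] = rng.gamma(post.shape, 1.0 / post.rate, size=draws)
        lam_matrix = per_season[:, season_idx]
        d_at_mean = deviance(series, posterior.means)
        tag: ModelTag = "seasonal"
    else:
        lam = rng.gamma(posterior.shape, 1.0 / posterior.rate, size=draws)
        lam_matrix = np.broadcast_to(lam[:, np.newaxis], (draws, J))
        d_at_mean = deviance(series, posterior.mean)
        tag = "homogeneous"
    dbar = float(_deviance_over_draws(series, lam_matrix).mean())
    p_d = dbar - d_at_mean
    return DicResult(dbar=dbar, d_at_mean=d_at_mean, p_d=p_d, dic=dbar + p_d, model_tag=tag)


def rolling_evaluation(
    series: AccrualSeries,
    prior: GammaRatePrior,
    model: ModelTag = "homogeneous",
    replicates_R: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> list[EvaluationResult]:
    """Rolling internal prediction for k = 1..J.

    For each k the model is refit on quarters 1..k and the remaining
    quarters are simulated with the shared-draw predictive scheme; each k
    uses an independent child stream of the master seed.  Seasons not yet
    observed at small k predict from the unmodified prior.  At k = J there
    is nothing left to predict and all three metrics are exactly zero.
    """
    if series.J < 1:
        raise ValueError("series must contain at least one quarter")
    if replicates_R < 2:
        raise ValueError(f"replicates_R must be >= 2 for the SD denominator, got {replicates_R}")
    m_true = series.total_count
    children = np.random.SeedSequence(seed).spawn(series.J)
    results: list[EvaluationResult] = []
    for k in range(1, series.J + 1):
        sub = series.head(k)
        future = tuple((q.season, q.duration) for q in series.quarters[k:])
        request = PredictiveRequest(
            future_quarters=future,
            observed_total=sub.total_count,
            replicates_R=replicates_R,
            seed=int(children[k - 1].generate_state(1)[0] % (2**31)),
        )
        if model == "homogeneous":
            draws = predict_total_homogeneous(update_homogeneous(prior, sub), request)
        elif model == "seasonal":
            draws = predict_total_seasonal(update_seasonal(prior, sub), request)
        else:
            raise ValueError(f"unknown model {model!r}")
        err = draws.totals.astype(float) - m_true
        rmse = float(np.sqrt(np.mean(err**2)))
        bias = float(np.mean(err))
        sd = float(np.std(draws.totals, ddof=1))
        results.append(
            EvaluationResult(
                k=k,
                rmse=rmse,
                bias=bias,
                sd=sd,
                model_tag=model,
                replicates_R=replicates_R,
                m_true=m_true,
            )
        )
    return results
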