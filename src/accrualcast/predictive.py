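"""Posterior predictive simulation of total accrual through a horizon.

Each simulation replicate draws rate value(s) from the posterior, simulates
Poisson counts for every remaining quarter, and adds them to the accrual
already observed.  Repeating this R times yields the posterior predictive
distribution of total accrual at the horizon.

Within a replicate a **single** rate draw is shared across all of that
replicate's future quarters (one draw per season in the seasonal model), so
future quarters are positively correlated through their common rate.  The
resulting predictive variance for the homogeneous model is

    Var(total) = (Σ t_j)·μ + (Σ t_j)²·σ²,

with μ, σ² the posterior mean and variance — wider than the independent
per-quarter-draw alternative, which is available via ``per_quarter_draws``
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .accrual_data import AccrualSeries, Season, season_cycle_from
from .conjugate import (
    DEFAULT_DRAWS,
    DEFAULT_SEED,
    GammaRatePosterior,
    SeasonalPosterior,
)

__all__ = [
    "PredictiveRequest",
    "PredictiveDraws",
    "PredictiveSummary",
    "predict_total_homogeneous",
    "predict_total_seasonal",
    "summarize_predictive",
]


@dataclass(frozen=True)
class PredictiveRequest:
    """What to simulate: future quarters, observed baseline, replication.

    ``future_quarters`` lists (season, duration) for quarters J+1..q.  Use
    :meth:`continue_series` to extend an observed series around the seasonal
    cycle automatically.
    """

    future_quarters: tuple[tuple[Season, float], ...]
    observed_total: int
    replicates_R: int = DEFAULT_DRAWS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        object.__setattr__(self, "future_quarters", tuple(self.future_quarters))
        if self.observed_total < 0:
            raise ValueError("observed_total must be non-negative")
        if self.replicates_R < 1:
            raise ValueError(f"replicates_R must be >= 1, got {self.replicates_R}")
        for s, t in self.future_quarters:
            if not 0 < t <= 1:
                raise ValueError(f"future quarter duration must lie in (0, 1], got {t}")

    @classmethod
    def continue_series(
        cls,
        series: AccrualSeries,
        horizon_q: int,
        observed_total: int | None = None,
        replicates_R: int = DEFAULT_DRAWS,
        seed: int = DEFAULT_SEED,
    ) -> "PredictiveRequest":
        """Request for total accrual after ``horizon_q`` quarters.

        Future seasons continue the cyclic order from the last observed
        quarter; future durations are 1.  ``observed_total`` defaults to the
        series total plus any excluded partial-quarter count, since excluded
        participants still count toward the trial's total enrollment.
        """
        if horizon_q < series.J:
            raise ValueError(f"horizon_q ({horizon_q}) must be >= observed J ({series.J})")
        n_future = horizon_q - series.J
        start = series.quarters[-1].season.next if series.J else Season.SUMMER
        seasons = season_cycle_from(start, n_future)
        if observed_total is None:
            observed_total = series.total_count + series.excluded_count
        return cls(
            future_quarters=tuple((s, 1.0) for s in seasons),
            observed_total=observed_total,
            replicates_R=replicates_R,
            seed=seed,
        )


@dataclass(frozen=True)
class PredictiveDraws:
    """R simulated horizon totals, each = observed_total + predicted future."""

    totals: np.ndarray
    observed_total: int
    seed: int

    @property
    def replicates(self) -> int:
        return int(self.totals.shape[0])

    @property
    def mean(self) -> float:
        return float(self.totals.mean())

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.totals, [tail, 1.0 - tail])
        return float(lo), float(hi)


@dataclass(frozen=True)
class PredictiveSummary:
    mean: float
    lower: float
    upper: float
    level: float
    replicates: int
    histogram: dict[int, int]


def _simulate(
    rate_matrix: np.ndarray,
    durations: np.ndarray,
    request: PredictiveRequest,
    rng: np.random.Generator,
) -> PredictiveDraws:
    """Poisson counts with means rate_matrix * durations, summed per replicate."""
    if rate_matrix.size:
        counts = rng.poisson(rate_matrix * durations[np.newaxis, :])
        future = counts.sum(axis=1)
    else:
        future = np.zeros(request.replicates_R, dtype=np.int64)
    totals = request.observed_total + future
    return PredictiveDraws(totals=totals, observed_total=request.observed_total, seed=request.seed)


def predict_total_homogeneous(
    posterior: GammaRatePosterior,
    request: PredictiveRequest,
    per_quarter_draws: bool = False,
) -> PredictiveDraws:
    """Simulate horizon totals under the constant-rate model.

    Default scheme: one λ* draw per replicate, shared by every future
    quarter of that replicate; ``per_quarter_draws`` instead draws a fresh
    λ* for each (replicate, quarter) cell.
    """
    rng = np.random.default_rng(request.seed)
    R = request.replicates_R
    Q = len(request.future_quarters)
    t = np.array([d for _, d in request.future_quarters], dtype=float)
    if Q == 0:
        return _simulate(np.empty((R, 0)), t, request, rng)
    scale = 1.0 / posterior.rate
    if per_quarter_draws:
        lam = rng.gamma(posterior.shape, scale, size=(R, Q))
    else:
        lam = rng.gamma(posterior.shape, scale, size=R)[:, np.newaxis]
        lam = np.broadcast_to(lam, (R, Q))
    return _simulate(lam, t, request, rng)


def predict_total_seasonal(
    posterior: SeasonalPosterior,
    request: PredictiveRequest,
    per_quarter_draws: bool = False,
) -> PredictiveDraws:
    """Simulate horizon totals with season-specific rates.

    One λ*_s per (replicate, season), shared by all future quarters of that
    season within the replicate; seasons never observed fall back to their
    prior-carrying posteriors automatically.
    """
    rng = np.random.default_rng(request.seed)
    R = request.replicates_R
    Q = len(request.future_quarters)
    t = np.array([d for _, d in request.future_quarters], dtype=float)
    if Q == 0:
        return _simulate(np.empty((R, 0)), t, request, rng)
    seasons = [s for s, _ in request.future_quarters]
    lam = np.empty((R, Q))
    for s in dict.fromkeys(seasons):  # preserve first-appearance order
        post = posterior[s]
        cols = [i for i, si in enumerate(seasons) if si is s]
        if per_quarter_draws:
            lam[:, cols] = rng.gamma(post.shape, 1.0 / post.rate, size=(R, len(cols)))
        else:
            lam[:, cols] = rng.gamma(post.shape, 1.0 / post.rate, size=R)[:, np.newaxis]
    return _simulate(lam, t, request, rng)


def summarize_predictive(draws: PredictiveDraws, level: float = 0.95) -> PredictiveSummary:
    """Mean, equal-tailed interval, and exact histogram of simulated totals."""
    if draws.totals.size == 0:
        raise ValueError("cannot summarize empty predictive draws")
    if not 0 < level < 1:
        raise ValueError(f"interval level must lie in (0, 1), got {level}")
    lo, hi = draws.interval(level)
    values, freqs = np.unique(draws.totals, return_counts=True)
    return PredictiveSummary(
        mean=draws.mean,
        lower=lo,
        upper=hi,
        level=level,
        replicates=draws.replicates,
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
    )
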