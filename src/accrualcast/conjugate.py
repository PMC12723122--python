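"""Prior elicitation and exact conjugate gamma-Poisson updates.

The accrual count in quarter ``j`` is modelled as ``m_j ~ Poisson(λ t_j)``
with a ``Gamma(α, β)`` prior on the rate λ.  β is a **rate** parameter: the
prior density is proportional to ``λ^{α-1} e^{-βλ}``, so the prior mean is
α/β.  Conjugacy gives the posterior in closed form,

    λ | data ~ Gamma(α + Σ m_j,  β + Σ t_j),

and in the seasonal model the same update is applied independently to each
season s over its own quarters J_s.  Because the posterior is available
exactly, posterior summaries and predictive simulation use direct i.i.d.
gamma sampling — no Markov chain, no burn-in.

Prior elicitation follows the planned-enrollment recipe: with a planned rate
of N/Q participants per quarter and a confidence weight p ∈ (0, 1],

    α = (N / Q) × p,   β = 1 × p,

which places p quarters' worth of pseudo-exposure at the planned rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats

from .accrual_data import SEASON_CYCLE, AccrualSeries, Season, season_sets

__all__ = [
    "GammaRatePrior",
    "GammaRatePosterior",
    "SeasonalPosterior",
    "PosteriorSummary",
    "elicit_prior",
    "update_homogeneous",
    "update_seasonal",
    "posterior_summary",
    "sample_rate",
]

DEFAULT_DRAWS = 10_000
DEFAULT_SEED = 20_18_06_25  # packaged default; every caller may override


@dataclass(frozen=True)
class GammaRatePrior:
    """Gamma(shape, rate) prior for an accrual rate λ (rate parameterization)."""

    shape: float
    rate: float
    confidence_p: float | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError(f"shape and rate must be positive, got ({self.shape}, {self.rate})")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class GammaRatePosterior:
    """Gamma(shape, rate) posterior for λ (or a season-specific λ_s)."""

    shape: float
    rate: float
    n_quarters_used: int = 0
    season: Season | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError(f"shape and rate must be positive, got ({self.shape}, {self.rate})")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval from the exact gamma quantiles."""
        _check_level(level)
        tail = (1.0 - level) / 2.0
        dist = stats.gamma(self.shape, scale=1.0 / self.rate)
        return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


@dataclass(frozen=True)
class SeasonalPosterior:
    """Independent per-season rate posteriors; all four seasons present.

    Seasons with no observed quarters carry the unmodified prior.
    """

    per_season: dict[Season, GammaRatePosterior]

    def __post_init__(self) -> None:
        if set(self.per_season) != set(Season):
            missing = set(Season) - set(self.per_season)
            raise ValueError(f"seasonal posterior missing seasons: {sorted(s.value for s in missing)}")

    def __getitem__(self, season: Season) -> GammaRatePosterior:
        return self.per_season[season]

    @property
    def means(self) -> dict[Season, float]:
        return {s: self.per_season[s].mean for s in SEASON_CYCLE}

    def prior_only_seasons(self) -> list[Season]:
        return [s for s in SEASON_CYCLE if self.per_season[s].n_quarters_used == 0]


def elicit_prior(
    target_enrollment: int,
    planned_quarters: int,
    confidence_p: float,
) -> GammaRatePrior:
    """Elicit Gamma(α, β) from planning inputs: α = (N/Q)·p, β = p.

    The prior mean α/β equals the planned per-quarter rate N/Q regardless of
    p; p controls how many quarters of pseudo-data the prior is worth.
    Shapes are returned unrounded; pass an explicit ``GammaRatePrior`` to
    reproduce published analyses that rounded the shape.
    """
    if target_enrollment <= 0 or planned_quarters <= 0:
        raise ValueError("target_enrollment and planned_quarters must be positive")
    if not 0 < confidence_p <= 1:
        raise ValueError(f"confidence_p must lie in (0, 1], got {confidence_p}")
    rate_per_quarter = target_enrollment / planned_quarters
    return GammaRatePrior(
        shape=rate_per_quarter * confidence_p,
        rate=1.0 * confidence_p,
        confidence_p=confidence_p,
    )


def update_homogeneous(prior: GammaRatePrior, series: AccrualSeries) -> GammaRatePosterior:
    """Exact conjugate update pooling all quarters: Gamma(α + Σm_j, β + Σt_j)."""
    return GammaRatePosterior(
        shape=prior.shape + series.total_count,
        rate=prior.rate + series.total_exposure,
        n_quarters_used=series.J,
    )


def update_seasonal(prior: GammaRatePrior, series: AccrualSeries) -> SeasonalPosterior:
    """Per-season conjugate updates with the same prior applied to each λ_s."""
    subsets = season_sets(series)
    per_season = {
        s: GammaRatePosterior(
            shape=prior.shape + sub.count,
            rate=prior.rate + sub.exposure,
            n_quarters_used=sub.n_quarters,
            season=s,
        )
        for s, sub in subsets.items()
    }
    return SeasonalPosterior(per_season)


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    lower: float
    upper: float
    level: float
    method: str


def _check_level(level: float) -> None:
    if not 0 < level < 1:
        raise ValueError(f"interval level must lie in (0, 1), got {level}")


def posterior_summary(
    posterior: GammaRatePosterior,
    level: float = 0.95,
    method: Literal["analytic", "monte_carlo"] = "analytic",
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> PosteriorSummary:
    """Posterior mean and equal-tailed credible interval.

    ``analytic`` uses the exact gamma mean and inverse-CDF quantiles;
    ``monte_carlo`` uses the empirical mean and quantiles of ``draws``
    i.i.d. posterior samples (mirroring summaries built from sampler output).
    """
    _check_level(level)
    if method == "analytic":
        lo, hi = posterior.interval(level)
        return PosteriorSummary(posterior.mean, lo, hi, level, "analytic")
    if method == "monte_carlo":
        x = sample_rate(posterior, draws=draws, seed=seed)
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(x, [tail, 1.0 - tail])
        return PosteriorSummary(float(x.mean()), float(lo), float(hi), level, "monte_carlo")
    raise ValueError(f"unknown summary method {method!r}")


def sample_rate(
    posterior: GammaRatePosterior,
    draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> np.ndarray:
    """``draws`` i.i.d. samples from the gamma posterior, reproducible by seed."""
    if draws < 1:
        raise ValueError(f"draws must be >= 1, got {draws}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.gamma(shape=posterior.shape, scale=1.0 / posterior.rate, size=draws)
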