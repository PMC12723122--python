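"""Posterior comparison of seasonal accrual rates.

Given independent gamma posteriors for the four seasonal rates λ_s, this
module computes pairwise exceedance probabilities P(λ_s > λ_k) and the
probability that each season has the highest (or lowest) rate.

All quantities for one posterior are evaluated on a single shared matrix of
joint draws, so the complement identity P(λ_s>λ_k) = 1 − P(λ_k>λ_s) and the
coherence bound prob_max(s) ≤ min_k P(λ_s>λ_k) hold exactly on the sample,
not merely in the limit.

The pairwise probability also has a closed form.  With λ_s ~ Gamma(a_s, b_s)
and λ_k ~ Gamma(a_k, b_k) independent (rate parameterization), the variable
B = b_s λ_s / (b_s λ_s + b_k λ_k) is Beta(a_s, a_k), and

    λ_s > λ_k  ⟺  B > b_s / (b_s + b_k),

so P(λ_s > λ_k) = 1 − I_{b_s/(b_s+b_k)}(a_s, a_k) with I the regularized
incomplete beta function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .accrual_data import SEASON_CYCLE, Season
from .conjugate import DEFAULT_DRAWS, DEFAULT_SEED, SeasonalPosterior

__all__ = [
    "SeasonComparison",
    "joint_rate_draws",
    "pairwise_prob",
    "pairwise_prob_closed_form",
    "prob_extreme_season",
    "compare_seasons",
]


@dataclass(frozen=True)
class SeasonComparison:
    """Pairwise exceedance table and extreme-season probabilities."""

    pairwise: dict[tuple[Season, Season], float]
    extreme: dict[Season, dict[str, float]]
    draws_used: int
    seed: int

    def prob_greater(self, s: Season, k: Season) -> float:
        return self.pairwise[(s, k)]

    def prob_max(self, s: Season) -> float:
        return self.extreme[s]["prob_max"]

    def prob_min(self, s: Season) -> float:
        return self.extreme[s]["prob_min"]

    def as_table(self) -> np.ndarray:
        """4x4 matrix P(row season > column season); diagonal is NaN."""
        tab = np.full((4, 4), np.nan)
        for i, s in enumerate(SEASON_CYCLE):
            for j, k in enumerate(SEASON_CYCLE):
                if s is not k:
                    tab[i, j] = self.pairwise[(s, k)]
        return tab


def joint_rate_draws(
    posterior: SeasonalPosterior,
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Shared 4 x draws matrix of joint rate samples, rows in cycle order."""
    if draws < 1:
        raise ValueError(f"draws must be >= 1, got {draws}")
    rng = np.random.default_rng(seed)
    out = np.empty((4, draws))
    for i, s in enumerate(SEASON_CYCLE):
        post = posterior[s]
        out[i] = rng.gamma(post.shape, 1.0 / post.rate, size=draws)
    return out


def pairwise_prob_closed_form(posterior: SeasonalPosterior, s: Season, k: Season) -> float:
    """Exact P(λ_s > λ_k) via the beta-transform identity (see module docs)."""
    if s is k:
        raise ValueError("seasons to compare must differ")
    ps, pk = posterior[s], posterior[k]
    threshold = ps.rate / (ps.rate + pk.rate)
    return float(stats.beta.sf(threshold, ps.shape, pk.shape))


def pairwise_prob(
    posterior: SeasonalPosterior,
    s: Season,
    k: Season,
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
    method: Literal["monte_carlo", "closed_form"] = "monte_carlo",
) -> float:
    """P(λ_s > λ_k) by Monte Carlo on joint draws or the exact closed form.

    Floating-point ties count as "not strictly greater".
    """
    if s is k:
        raise ValueError("seasons to compare must differ")
    if method == "closed_form":
        return pairwise_prob_closed_form(posterior, s, k)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    m = joint_rate_draws(posterior, draws=draws, seed=seed)
    i, j = SEASON_CYCLE.index(s), SEASON_CYCLE.index(k)
    return float(np.mean(m[i] > m[j]))


def compare_seasons(
    posterior: SeasonalPosterior,
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> SeasonComparison:
    """All pairwise and extreme-season probabilities from one joint sample."""
    m = joint_rate_draws(posterior, draws=draws, seed=seed)
    pairwise: dict[tuple[Season, Season], float] = {}
    for i, s in enumerate(SEASON_CYCLE):
        for j, k in enumerate(SEASON_CYCLE):
            if i < j:
                p = float(np.mean(m[i] > m[j]))
                pairwise[(s, k)] = p
                pairwise[(k, s)] = 1.0 - p
    argmax = m.argmax(axis=0)
    argmin = m.argmin(axis=0)
    extreme = {
        s: {
            "prob_max": float(np.mean(argmax == i)),
            "prob_min": float(np.mean(argmin == i)),
        }
        for i, s in enumerate(SEASON_CYCLE)
    }
    return SeasonComparison(pairwise=pairwise, extreme=extreme, draws_used=draws, seed=seed)


def prob_extreme_season(
    posterior: SeasonalPosterior,
    draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
) -> dict[Season, dict[str, float]]:
    """Per season, the probability its rate is the strict max (and min)."""
    return compare_seasons(posterior, draws=draws, seed=seed).extreme
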