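"""Posterior predictive simulation: mean/variance laws and the shared-draw scheme."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from accrualcast import (
    GammaRatePosterior,
    PredictiveRequest,
    Season,
    SeasonalPosterior,
    predict_total_homogeneous,
    predict_total_seasonal,
    summarize_predictive,
    update_homogeneous,
    update_seasonal,
)
from accrualcast.accrual_data import season_cycle_from


def unit_request(n_future, observed, R=10_000, seed=1234, start=Season.WINTER):
    seasons = season_cycle_from(start, n_future)
    return PredictiveRequest(
        future_quarters=tuple((s, 1.0) for s in seasons),
        observed_total=observed,
        replicates_R=R,
        seed=seed,
    )


class TestHomogeneousPrediction:
    def test_slow_trial_horizon_mean(self, hobit_prior, hobit_series):
        post = update_homogeneous(hobit_prior, hobit_series)
        draws = predict_total_homogeneous(post, unit_request(10, observed=139))
        # analytic expectation: 139 + 10 * posterior mean = 193.81
        assert draws.mean == pytest.approx(193.81, abs=1.0)

    def test_fast_trial_horizon_mean(self, boost3_prior, boost3_series):
        post = update_homogeneous(boost3_prior, boost3_series)
        draws = predict_total_homogeneous(post, unit_request(9, observed=725))
        assert draws.mean == pytest.approx(725 + 9 * post.mean, abs=2.5)

    def test_zero_future_quarters_degenerate(self):
        post = GammaRatePosterior(10.0, 2.0)
        draws = predict_total_homogeneous(post, unit_request(0, observed=42))
        assert np.all(draws.totals == 42)
        assert draws.interval() == (42.0, 42.0)

    def test_lower_bound_is_observed_total(self):
        post = GammaRatePosterior(3.0, 0.5)
        draws = predict_total_homogeneous(post, unit_request(8, observed=17))
        assert draws.totals.min() >= 17

    def test_mean_law_large_R(self):
        """Predictive mean converges to obs + Σt·(posterior mean)."""
        post = GammaRatePosterior(145.25, 26.5)
        R = 1_000_000
        draws = predict_total_homogeneous(post, unit_request(10, observed=139, R=R, seed=5))
        T = 10.0
        var = T * post.mean + T**2 * post.variance
        assert abs(draws.mean - (139 + T * post.mean)) < 4 * math.sqrt(var / R)

    def test_variance_law_shared_draw(self):
        """Shared-draw scheme: Var = Σt·μ + (Σt)²·σ² (wider than per-quarter)."""
        post = GammaRatePosterior(145.25, 26.5)
        R = 400_000
        shared = predict_total_homogeneous(post, unit_request(10, observed=0, R=R, seed=6))
        T = 10.0
        expected = T * post.mean + T**2 * post.variance
        # sample variance of ~normal totals: SE ≈ var·sqrt(2/R)
        assert shared.totals.var(ddof=1) == pytest.approx(expected, rel=4 * math.sqrt(2 / R) + 0.01)

    def test_per_quarter_draw_mode_is_narrower(self):
        post = GammaRatePosterior(145.25, 26.5)
        req = unit_request(10, observed=0, R=100_000, seed=8)
        shared = predict_total_homogeneous(post, req)
        independent = predict_total_homogeneous(post, req, per_quarter_draws=True)
        assert independent.totals.var(ddof=1) < shared.totals.var(ddof=1)

    def test_seed_reproducibility_bitwise(self):
        post = GammaRatePosterior(20.0, 3.0)
        req = unit_request(5, observed=9, R=2_000, seed=99)
        a = predict_total_homogeneous(post, req)
        b = predict_total_homogeneous(post, req)
        assert np.array_equal(a.totals, b.totals)

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates_R"):
            unit_request(3, observed=0, R=0)


class TestSeasonalPrediction:
    def test_slow_trial_seasonal_horizon(self, hobit_prior, hobit_series):
        post = update_seasonal(hobit_prior, hobit_series)
        req = PredictiveRequest.continue_series(hobit_series, 36, replicates_R=20_000, seed=3)
        draws = predict_total_seasonal(post, req)
        # 3 winter + 3 spring + 2 summer + 2 fall future quarters
        expected = 139 + sum(
            post[s].mean * n
            for s, n in [(Season.WINTER, 3), (Season.SPRING, 3), (Season.SUMMER, 2), (Season.FALL, 2)]
        )
        assert draws.mean == pytest.approx(expected, abs=1.0)
        lo, hi = draws.interval(0.95)
        assert lo == pytest.approx(178, abs=4)
        assert hi == pytest.approx(213, abs=4)

    def test_fast_trial_seasonal_horizon(self, boost3_prior, boost3_series):
        post = update_seasonal(boost3_prior, boost3_series)
        req = PredictiveRequest.continue_series(
            boost3_series, 30, observed_total=725, replicates_R=20_000, seed=4
        )
        draws = predict_total_seasonal(post, req)
        assert draws.mean == pytest.approx(1060, abs=4)

    def test_identical_season_posteriors_match_homogeneous(self):
        """Degenerate seasonal model reduces to the homogeneous predictive.

        Equality requires the same rate-sharing structure: either every
        future quarter lies in one season (so the shared-draw schemes
        coincide), or both models redraw the rate per quarter.
        """
        post = GammaRatePosterior(50.0, 10.0)
        seasonal = SeasonalPosterior({s: post for s in Season})
        one_season = PredictiveRequest(
            future_quarters=((Season.FALL, 1.0),) * 6, observed_total=0,
            replicates_R=40_000, seed=21,
        )
        a = predict_total_seasonal(seasonal, one_season)
        b = predict_total_homogeneous(
            post, PredictiveRequest(one_season.future_quarters, 0, 40_000, seed=22)
        )
        assert stats.ks_2samp(a.totals, b.totals).pvalue > 1e-4

        mixed = unit_request(8, observed=0, R=40_000, seed=23)
        a = predict_total_seasonal(seasonal, mixed, per_quarter_draws=True)
        b = predict_total_homogeneous(
            post, unit_request(8, observed=0, R=40_000, seed=24), per_quarter_draws=True
        )
        assert stats.ks_2samp(a.totals, b.totals).pvalue > 1e-4

    def test_continue_series_includes_excluded_count(self, boost3_series):
        from dataclasses import replace

        series = replace(boost3_series, excluded_count=1)
        req = PredictiveRequest.continue_series(series, 30)
        assert req.observed_total == 725
        # future seasons continue the cycle from the last observed quarter (fall)
        assert req.future_quarters[0][0] is Season.WINTER
        assert len(req.future_quarters) == 9


class TestSummaries:
    def test_constant_draws(self):
        post = GammaRatePosterior(4.0, 1.0)
        summ = summarize_predictive(predict_total_homogeneous(post, unit_request(0, observed=7)))
        assert (summ.mean, summ.lower, summ.upper) == (7.0, 7.0, 7.0)
        assert summ.histogram == {7: summ.replicates}

    def test_histogram_accounting_identity(self, hobit_prior, hobit_series):
        post = update_homogeneous(hobit_prior, hobit_series)
        draws = predict_total_homogeneous(post, unit_request(10, observed=139, R=5_000))
        summ = summarize_predictive(draws)
        assert sum(summ.histogram.values()) == draws.replicates
        mean_from_hist = sum(v * f for v, f in summ.histogram.items()) / draws.replicates
        assert mean_from_hist == pytest.approx(summ.mean)

    def test_slow_trial_homogeneous_interval(self, hobit_prior, hobit_series):
        post = update_homogeneous(hobit_prior, hobit_series)
        summ = summarize_predictive(
            predict_total_homogeneous(post, unit_request(10, observed=139, R=20_000, seed=17))
        )
        assert summ.lower == pytest.approx(178, abs=3)
        assert summ.upper == pytest.approx(211, abs=3)
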