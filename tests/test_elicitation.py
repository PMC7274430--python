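"""Evidence-to-prior conversions: percentile fits, likelihoods, pooling."""

import math

import numpy as np
import pytest
from scipy import stats

from ebis.elicitation import (
    EffectEstimate,
    IndicatorScale,
    annual_prob_from_frequency,
    combine_likelihood_estimates,
    count_drought_events,
    fit_beta_from_percentiles,
    fit_normal_from_percentiles,
    pool_effect_estimates,
    prob_from_indicator_scale,
    relative_to_absolute_income,
)
from ebis.model_config import DistributionSpec


class TestNormalPercentileFit:
    def test_beneficiary_pool_fit(self):
        d = fit_normal_from_percentiles(168_000, 280_000, 0.01, 0.99)
        assert d.params["mean"] == pytest.approx(224_000, abs=1e-6)
        # sd = half-range / z(0.99), checked against an independent quantile
        z99 = stats.norm.ppf(0.99)
        assert d.params["sd"] == pytest.approx(56_000 / z99, rel=1e-12)

    def test_cdf_residuals_below_1e9(self):
        d = fit_normal_from_percentiles(168_000, 280_000, 0.01, 0.99)
        assert abs(d.cdf(168_000) - 0.01) < 1e-9
        assert abs(d.cdf(280_000) - 0.99) < 1e-9

    @pytest.mark.parametrize("a,p", [(1.0, 0.05), (17.3, 0.01), (0.2, 0.2)])
    def test_symmetric_percentiles_give_zero_mean(self, a, p):
        d = fit_normal_from_percentiles(-a, a, p, 1 - p)
        assert d.params["mean"] == pytest.approx(0.0, abs=1e-12 * a)

    def test_unordered_values_rejected(self):
        with pytest.raises(ValueError):
            fit_normal_from_percentiles(10.0, 5.0, 0.01, 0.99)
        with pytest.raises(ValueError):
            fit_normal_from_percentiles(5.0, 10.0, 0.99, 0.01)


class TestBetaPercentileFit:
    def test_cdf_residuals_below_1e6(self):
        d = fit_beta_from_percentiles(0.05, 0.15, 0.01, 0.99)
        assert d.family == "beta"
        assert abs(d.cdf(0.05) - 0.01) < 1e-6
        assert abs(d.cdf(0.15) - 0.99) < 1e-6

    def test_symmetry_about_half_gives_equal_shapes(self):
        d = fit_beta_from_percentiles(0.3, 0.7, 0.05, 0.95)
        assert d.params["alpha"] == pytest.approx(d.params["beta"], rel=1e-6)

    def test_unordered_values_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_from_percentiles(0.3, 0.2, 0.01, 0.99)


class TestAnnualProbability:
    @pytest.mark.parametrize("count,span,expected", [
        (1, 10, 0.10),   # one event per decade
        (5, 100, 0.05),  # five events per century
        (0, 20, 0.0),
        (30, 20, 1.0),   # capped
    ])
    def test_frequency_to_probability(self, count, span, expected):
        assert annual_prob_from_frequency(count, span) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_homogeneous_in_scale(self, k):
        assert annual_prob_from_frequency(3 * k, 40 * k) == pytest.approx(
            annual_prob_from_frequency(3, 40))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            annual_prob_from_frequency(-1, 10)
        with pytest.raises(ValueError):
            annual_prob_from_frequency(1, 0)


class TestIndicatorScale:
    def test_certain_anchor_maps_to_one(self):
        p, _ = prob_from_indicator_scale(-3.0, 0.0, IndicatorScale(-3.0, 2.0))
        assert p == 1.0

    def test_impossible_anchor_maps_to_zero(self):
        p, _ = prob_from_indicator_scale(4.0, 0.0, IndicatorScale(0.0, 4.0))
        assert p == 0.0

    def test_midpoint_interpolates_linearly(self):
        # anchors -3 -> 1 and 2 -> 0; -0.5 is exactly halfway
        p, _ = prob_from_indicator_scale(-0.5, 0.0, IndicatorScale(-3.0, 2.0))
        assert p == pytest.approx(0.5)

    def test_sd_maps_by_absolute_slope(self):
        _, sd = prob_from_indicator_scale(0.0, 1.5, IndicatorScale(-3.0, 2.0))
        assert sd == pytest.approx(1.5 / 5.0)

    def test_clamping_outside_anchors(self):
        scale = IndicatorScale(-3.0, 2.0)
        assert prob_from_indicator_scale(-5.0, 0.0, scale)[0] == 1.0
        assert prob_from_indicator_scale(3.0, 0.0, scale)[0] == 0.0

    @pytest.mark.parametrize("shift", [-2.0, 0.0, 5.5])
    def test_mapped_sd_invariant_to_anchor_shift(self, shift):
        base = IndicatorScale(-3.0, 2.0)
        shifted = IndicatorScale(-3.0 + shift, 2.0 + shift)
        _, sd0 = prob_from_indicator_scale(0.0, 0.8, base)
        _, sd1 = prob_from_indicator_scale(shift, 0.8, shifted)
        assert sd1 == pytest.approx(sd0)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            IndicatorScale(1.0, 1.0)


def _one_dip_series():
    x = np.full(48, 100.0)
    x[24:30] = 40.0
    return x


def _two_dip_series():
    x = np.full(84, 100.0)
    x[24:30] = 40.0
    x[60:66] = 40.0
    return x


class TestDroughtCounting:
    def test_constant_series_has_no_events(self):
        assert count_drought_events(np.full(36, 80.0)) == 0

    def test_single_engineered_deficit(self):
        # oracle: independent pandas rolling-sum z-score scan gives 1 event
        assert count_drought_events(_one_dip_series()) == 1

    def test_two_disjoint_deficits(self):
        # oracle: same independent scan gives 2 events
        assert count_drought_events(_two_dip_series()) == 2

    @pytest.mark.parametrize("k", [0.01, 3.0, 1000.0])
    def test_invariant_to_positive_rescaling(self, k):
        assert count_drought_events(_two_dip_series() * k) == 2

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_drought_events(np.full(23, 100.0))


class TestCombineLikelihoods:
    def test_mean_of_pest_estimates(self):
        d = combine_likelihood_estimates([0.05, 0.25], method="mean")
        assert d.family == "point"
        assert d.params["value"] == pytest.approx(0.15)

    def test_uniform_interval_midpoint(self):
        d = combine_likelihood_estimates([0.05, 0.25], method="uniform_interval")
        assert d.family == "uniform"
        assert (d.params["low"], d.params["high"]) == (0.05, 0.25)
        assert d.mean() == pytest.approx(0.15)

    @pytest.mark.parametrize("method", ["mean", "uniform_interval"])
    def test_singleton_is_point(self, method):
        d = combine_likelihood_estimates([0.1], method=method)
        assert d.family == "point"
        assert d.params["value"] == pytest.approx(0.1)

    def test_empty_or_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_likelihood_estimates([])
        with pytest.raises(ValueError):
            combine_likelihood_estimates([0.5, 1.2])


class TestEffectPooling:
    def test_single_estimate_unchanged(self):
        e = EffectEstimate(42.0, 7.0, "only")
        assert pool_effect_estimates([e], model="fixed") is e

    def test_equal_sd_fixed_is_arithmetic_mean(self):
        pooled = pool_effect_estimates(
            [EffectEstimate(40.0, 10.0), EffectEstimate(60.0, 10.0)], model="fixed")
        assert pooled.mean == pytest.approx(50.0)
        assert pooled.sd == pytest.approx(10.0 / math.sqrt(2))

    def test_random_effects_matches_hand_computation(self):
        # frozen from an independent step-by-step DerSimonian-Laird
        # computation: w=1/sd^2, Q=20.8278, C=0.0626667, tau^2=300.443
        estimates = [EffectEstimate(30.0, 5.0), EffectEstimate(70.0, 10.0),
                     EffectEstimate(55.0, 4.0)]
        pooled = pool_effect_estimates(estimates, model="random")
        assert pooled.mean == pytest.approx(50.49147606701683, rel=1e-12)
        assert pooled.sd == pytest.approx(10.70263372233817, rel=1e-12)

    def test_fixed_pooled_se_not_above_smallest_sd(self):
        estimates = [EffectEstimate(10.0, 3.0), EffectEstimate(12.0, 8.0),
                     EffectEstimate(9.0, 5.0)]
        pooled = pool_effect_estimates(estimates, model="fixed")
        assert pooled.sd <= 3.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_effect_estimates([])


class TestRelativeIncome:
    def test_point_product(self):
        desc = relative_to_absolute_income(
            DistributionSpec.point(100.0), DistributionSpec.point(1.463))
        assert desc.mean() == pytest.approx(146.3)

    def test_identity_multiplier_preserves_baseline(self):
        base = DistributionSpec.normal(500.0, 50.0)
        desc = relative_to_absolute_income(base, DistributionSpec.point(1.0))
        rng = np.random.default_rng(7)
        draws = np.array([desc.sample(rng) for _ in range(4000)])
        # distributed exactly as the baseline: matching moments
        assert draws.mean() == pytest.approx(500.0, abs=3 * 50.0 / math.sqrt(4000))

    def test_product_mean_within_monte_carlo_error(self):
        mu, sigma, c, n = 200.0, 20.0, 1.8, 20_000
        desc = relative_to_absolute_income(
            DistributionSpec.normal(mu, sigma), DistributionSpec.point(c))
        rng = np.random.default_rng(11)
        draws = np.array([desc.sample(rng) for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - c * mu) < 3 * se

    def test_invalid_input_distribution_rejected(self):
        with pytest.raises(ValueError):
            relative_to_absolute_income(
                DistributionSpec.normal(100.0, -1.0), DistributionSpec.point(1.0))
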