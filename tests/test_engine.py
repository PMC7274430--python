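"""Monte-Carlo engine: Bass curve, risk sampling, value chain, conditioning."""

import dataclasses
import math

import numpy as np
import pytest

from ebis.engine import (
    EmptyConditionalError,
    adoption_rate_bass,
    condition_result,
    run_monte_carlo,
    sample_risk_realization,
    simulate_draw,
)
from ebis.fixtures import make_point_mass_fixture, make_random_fixture
from ebis.model_config import (
    AdoptionSpec,
    DistributionSpec,
    NaturalRiskFactor,
    SpecValidationError,
)
from ebis.scenarios import ScenarioSpec, standard_scenarios

NO_RISKS = standard_scenarios()[0]


class TestBassCurve:
    @pytest.mark.parametrize("p,q", [(0.03, 0.38), (0.5, 0.0), (0.001, 2.0)])
    def test_zero_at_year_zero(self, p, q):
        assert adoption_rate_bass(p, q, 0.0) == 0.0

    def test_asymptote_is_one(self):
        assert adoption_rate_bass(0.03, 0.38, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        # independent arithmetic evaluation of the closed form for
        # P=0.01, Q=0.50, t=5 (scratch second implementation)
        assert adoption_rate_bass(0.01, 0.50, 5) == pytest.approx(
            0.1879899417671, rel=1e-10)

    def test_nonpositive_innovation_rejected(self):
        with pytest.raises(ValueError):
            adoption_rate_bass(0.0, 0.5, 1)
        with pytest.raises(ValueError):
            adoption_rate_bass(-0.1, 0.5, 1)

    def test_monotone_nondecreasing(self):
        years = np.arange(0, 30)
        for p, q in [(0.02, 0.4), (0.3, 0.0), (0.05, 1.5)]:
            vals = [adoption_rate_bass(p, q, t) for t in years]
            assert all(b >= a for a, b in zip(vals, vals[1:]))


def _one_natural_risk_spec(point_mass_spec, probabilities):
    risks = tuple(
        NaturalRiskFactor(
            name=f"hazard-{i}", annual_probability=p,
            beneficiary_income_multiplier=DistributionSpec.point(0.5),
            baseline_income_multiplier=DistributionSpec.point(0.5))
        for i, p in enumerate(probabilities))
    return point_mass_spec.replace(natural_risks=risks)


class TestRiskSampling:
    def test_deactivated_categories_always_none(self, case_spec):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r = sample_risk_realization(case_spec, NO_RISKS, rng)
            assert r.adoption_state is None
            assert r.financial_state is None
            assert all(s is None for s in r.natural_states)

    def test_single_factor_frequency(self, point_mass_spec):
        spec = _one_natural_risk_spec(point_mass_spec, [0.3])
        rng = np.random.default_rng(123)
        n = 100_000
        hits = sum(
            sample_risk_realization(spec, None, rng).natural_states[0] == 0
            for _ in range(n))
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(hits / n - 0.3) < 3 * se

    def test_none_state_is_complement(self, point_mass_spec):
        spec = _one_natural_risk_spec(point_mass_spec, [0.3, 0.2])
        rng = np.random.default_rng(7)
        n = 100_000
        none = sum(
            sample_risk_realization(spec, None, rng).natural_states[0] is None
            for _ in range(n))
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(none / n - 0.5) < 3 * se

    def test_natural_states_length_matches_period(self, case_spec):
        r = sample_risk_realization(case_spec, None, np.random.default_rng(1))
        assert len(r.natural_states) == case_spec.evaluation_period


class TestDeterministicValueChain:
    """Point-mass toy against hand arithmetic, zero tolerance."""

    def test_baseline_npv_and_roi(self):
        spec = make_point_mass_fixture().spec
        d = simulate_draw(spec, None, np.random.default_rng(0))
        assert d.npv == 45_000.0
        assert d.roi == 1.5
        assert d.adopters == (500.0, 1000.0)
        assert d.impact == (25_000.0, 50_000.0)
        assert d.over_budget_flag == (0, 0)

    def test_over_budget_variant(self):
        spec = make_point_mass_fixture(budget=15_000.0).spec
        d = simulate_draw(spec, None, np.random.default_rng(0))
        assert d.over_budget_flag == (1, 1)
        assert d.adjusted_impact == (12_500.0, 25_000.0)
        assert d.discounted_benefit == (-7_500.0, 15_000.0)
        assert d.npv == 7_500.0

    def test_discounted_variant(self):
        spec = make_point_mass_fixture(discount_rate=0.1).spec
        d = simulate_draw(spec, None, np.random.default_rng(0))
        assert d.discounted_benefit[0] == pytest.approx(5_000.0 / 1.1, abs=1e-9)
        assert d.discounted_benefit[1] == pytest.approx(40_000.0 / 1.21, abs=1e-9)
        assert d.npv == pytest.approx(37_603.30578512396, abs=1e-9)

    def test_roi_undefined_when_costs_zero(self, point_mass_spec):
        finance = dataclasses.replace(
            point_mass_spec.finance,
            yearly_costs=(DistributionSpec.point(0.0), DistributionSpec.point(0.0)))
        d = simulate_draw(point_mass_spec.replace(finance=finance), None,
                          np.random.default_rng(0))
        assert not d.roi_defined
        assert math.isnan(d.roi)

    def test_discounted_roi_denominator(self):
        spec = make_point_mass_fixture(discount_rate=0.1).spec
        spec = spec.replace(finance=dataclasses.replace(
            spec.finance, roi_denominator="discounted"))
        d = simulate_draw(spec, None, np.random.default_rng(0))
        denom = 20_000.0 / 1.1 + 10_000.0 / 1.21
        assert d.roi == pytest.approx(d.npv / denom)


from helpers import closed_form_expected_npv, linear_spec as _linear_spec


class TestMonteCarlo:
    def test_point_mass_draws_all_identical(self, point_mass_spec):
        res = run_monte_carlo(point_mass_spec, None, 50, seed=3)
        assert all(d.npv == 45_000.0 and d.roi == 1.5 for d in res.draws)

    def test_bit_identical_reruns(self, case_spec):
        a = run_monte_carlo(case_spec, None, 300, seed=42)
        b = run_monte_carlo(case_spec, None, 300, seed=42)
        assert a.draws == b.draws

    def test_prefix_stable_in_n(self, case_spec):
        small = run_monte_carlo(case_spec, None, 50, seed=5)
        big = run_monte_carlo(case_spec, None, 120, seed=5)
        assert big.draws[:50] == small.draws

    def test_linear_spec_mean_matches_closed_form(self, point_mass_spec):
        spec = _linear_spec(point_mass_spec)
        n = 20_000
        res = run_monte_carlo(spec, None, n, seed=17)
        npv = res.npv_values()
        se = npv.std(ddof=1) / math.sqrt(n)
        assert abs(npv.mean() - closed_form_expected_npv(spec)) < 3 * se

    def test_invalid_spec_rejected_before_sampling(self, point_mass_spec):
        bad = point_mass_spec.replace(evaluation_period=0)
        with pytest.raises(SpecValidationError):
            run_monte_carlo(bad, None, 10, seed=0)

    def test_invalid_n_rejected(self, point_mass_spec):
        with pytest.raises(ValueError):
            run_monte_carlo(point_mass_spec, None, 0, seed=0)


class TestDrawInvariants:
    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_budget_flag_monotone_and_roi_identity(self, seed):
        spec = make_random_fixture(seed, "medium").spec
        res = run_monte_carlo(spec, None, 400, seed=seed + 100)
        d_rate = spec.finance.discount_rate
        for d in res.draws:
            flags = d.over_budget_flag
            assert all(b >= a for a, b in zip(flags, flags[1:]))
            if d.roi_defined:
                if spec.finance.roi_denominator == "discounted":
                    denom = sum(c / (1 + d_rate) ** (t + 1)
                                for t, c in enumerate(d.cost))
                else:
                    denom = sum(d.cost)
                assert d.roi * denom == pytest.approx(d.npv, rel=1e-12, abs=1e-9)
            assert all(0.0 <= a <= 1.0 for a in d.adoption_fraction)
            assert d.adopters == tuple(
                a * d.realized_pool for a in d.adoption_fraction)

    def test_bass_mode_adoption_nondecreasing(self, point_mass_spec):
        adoption = AdoptionSpec(
            mode="bass",
            target_pool=DistributionSpec.point(1000.0),
            innovation_rate=DistributionSpec.uniform(0.01, 0.08),
            imitation_rate=DistributionSpec.uniform(0.1, 0.6),
        )
        spec = point_mass_spec.replace(adoption=adoption, evaluation_period=2)
        res = run_monte_carlo(spec, None, 300, seed=2)
        for d in res.draws:
            ar = d.adoption_fraction
            assert all(b >= a for a, b in zip(ar, ar[1:]))
            assert ar[0] > 0.0

    def test_adoption_risk_multipliers_reduce_expected_npv(self, case_spec):
        # all adoption-risk effects in the case fixture are <= 1 multipliers
        natural_off_all_adoption = ScenarioSpec(
            "adoption only", natural_active=False, financial_active=False)
        no_risk = ScenarioSpec("none", natural_active=False, adoption_active=False,
                               financial_active=False)
        with_risk = run_monte_carlo(case_spec, natural_off_all_adoption, 4000, seed=21)
        without = run_monte_carlo(case_spec, no_risk, 4000, seed=22)
        se = math.sqrt(with_risk.npv_values().var(ddof=1) / 4000
                       + without.npv_values().var(ddof=1) / 4000)
        assert with_risk.npv_values().mean() < without.npv_values().mean() + 3 * se


class TestConditioning:
    def test_always_true_predicate_keeps_everything(self, case_spec):
        res = run_monte_carlo(case_spec, None, 200, seed=1)
        cond = condition_result(res, lambda d: True)
        assert cond.draws == res.draws

    def test_empty_conditional_raises(self, point_mass_spec):
        res = run_monte_carlo(point_mass_spec, None, 50, seed=1)
        with pytest.raises(EmptyConditionalError):
            condition_result(res, lambda d: d.npv < 0)

    def test_conditioning_matches_forced_state(self, case_spec):
        """Rejection conditioning on a risk state agrees with forcing the
        state's probability to 1 (within Monte-Carlo error)."""
        n = 6000
        res = run_monte_carlo(case_spec, None, n, seed=33)
        cond = condition_result(res, lambda d: d.risk.adoption_state == 0)
        forced_scenario = ScenarioSpec(
            "forced", overrides={
                case_spec.adoption_risks[0].name: 1.0,
                case_spec.adoption_risks[1].name: 0.0,
                case_spec.adoption_risks[2].name: 0.0,
            })
        forced = run_monte_carlo(case_spec, forced_scenario, n, seed=34)
        a, b = cond.npv_values(), forced.npv_values()
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se
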