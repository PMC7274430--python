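"""Shared test constructions with independently computable expectations."""

import dataclasses

from ebis.model_config import AdoptionSpec, DistributionSpec


def linear_spec(point_mass_spec):
    """A risk-free spec with no possible budget exceedance and distributions
    far from the clamping boundary, so E[NPV] has a closed form by
    independence and linearity of the value chain."""
    adoption = AdoptionSpec(
        mode="direct",
        target_pool=DistributionSpec.normal(1000.0, 50.0, "persons"),
        yearly_rates=(DistributionSpec.beta(8.0, 8.0), DistributionSpec.beta(12.0, 4.0)),
    )
    impact = dataclasses.replace(
        point_mass_spec.impact,
        baseline_income=DistributionSpec.normal(100.0, 5.0),
        adopter_income=DistributionSpec.normal(160.0, 8.0),
        ghg_balance=DistributionSpec.point(0.5),
        ghg_cost=DistributionSpec.point(4.0),
    )
    finance = dataclasses.replace(
        point_mass_spec.finance,
        budget=DistributionSpec.point(10_000_000.0),
        yearly_costs=(DistributionSpec.uniform(15_000.0, 25_000.0),
                      DistributionSpec.uniform(8_000.0, 12_000.0)),
        discount_rate=0.08,
    )
    return point_mass_spec.replace(adoption=adoption, impact=impact, finance=finance)


def closed_form_expected_npv(spec):
    """E[NPV] = sum_t (E[AR_t] E[TB] (E[IP] - E[IB] + E[CL]) - E[C_t]) / (1+d)^t,
    valid when risks are absent, the budget can never be exceeded and no
    sample can be clamped."""
    ar_means = [d.mean() for d in spec.adoption.yearly_rates]
    tb = spec.adoption.target_pool.mean()
    gain = (spec.impact.adopter_income.mean() - spec.impact.baseline_income.mean()
            + spec.impact.ghg_balance.mean() * spec.impact.ghg_cost.mean())
    d = spec.finance.discount_rate
    return sum(
        (ar_means[t] * tb * gain - spec.finance.yearly_costs[t].mean())
        / (1 + d) ** (t + 1)
        for t in range(spec.evaluation_period))
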