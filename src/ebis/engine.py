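"""Generative model and Monte-Carlo inference.

The model is a per-year fragment rolled forward over the evaluation period:
risk states select mixture components for adoption, income and budget
quantities; the deterministic value chain (beneficiaries -> impact ->
budget-overrun adjustment -> discounted benefit) then yields NPV and ROI for
each draw.  Inference is seeded forward sampling; backward queries (e.g. the
distribution of risk states given a negative NPV) are answered by filtering
the forward draws with :func:`condition_result`.

Sampling granularity: project-lifetime quantities (target pool, incomes,
GHG terms, budget, Bass parameters, adoption and financial risk states, and
any adoption/financial risk multipliers) are drawn once per draw; annual
quantities (natural risk states, income multipliers, direct-mode adoption
rates, costs) are drawn per year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_config import (
    DistributionSpec,
    EffectSpec,
    ProjectSpec,
    SpecValidationError,
    validate_project_spec,
)
from .scenarios import ScenarioSpec, apply_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "RiskRealization",
    "DrawTrajectory",
    "SimulationResult",
    "EmptyConditionalError",
    "adoption_rate_bass",
    "sample_risk_realization",
    "simulate_draw",
    "run_monte_carlo",
    "condition_result",
]


class EmptyConditionalError(RuntimeError):
    """No draw satisfied the conditioning predicate; rerun with larger n."""


@dataclass(frozen=True)
class RiskRealization:
    """Sampled risk states for one draw.

    ``adoption_state`` and ``financial_state`` are indices into the spec's
    factor lists (or None for the no-risk state) and hold for the whole
    project; ``natural_states`` holds one index-or-None per year.
    """

    adoption_state: int | None
    financial_state: int | None
    natural_states: tuple[int | None, ...]


@dataclass(frozen=True)
class DrawTrajectory:
    """One Monte-Carlo draw: per-year quantities plus NPV/ROI.

    All per-year sequences have length m (year t of the model is index
    t-1 here).  ``roi`` is NaN with ``roi_defined=False`` when the cost
    denominator is zero.
    """

    adoption_fraction: tuple[float, ...]
    adopters: tuple[float, ...]
    beneficiary_multiplier: tuple[float, ...]
    baseline_multiplier: tuple[float, ...]
    productivity_impact: tuple[float, ...]
    impact: tuple[float, ...]
    cost: tuple[float, ...]
    over_budget_flag: tuple[int, ...]
    adjusted_impact: tuple[float, ...]
    discounted_benefit: tuple[float, ...]
    climate_impact: float
    realized_pool: float
    realized_budget: float
    npv: float
    roi: float
    roi_defined: bool
    risk: RiskRealization


@dataclass
class SimulationResult:
    """A set of draws from one (spec, scenario) simulation.

    ``weights`` is None for plain forward sampling (uniform weights);
    conditioning keeps it explicit on the filtered sub-population.
    """

    draws: list[DrawTrajectory]
    n: int
    seed: int
    scenario_name: str
    weights: np.ndarray | None = None
    clamped_negative_draws: int = 0

    def npv_values(self) -> np.ndarray:
        return np.array([d.npv for d in self.draws], dtype=float)

    def roi_values(self) -> np.ndarray:
        return np.array([d.roi for d in self.draws], dtype=float)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.draws), dtype=float)
        return np.asarray(self.weights, dtype=float)


def adoption_rate_bass(innovation: float, imitation: float, year: float) -> float:
    """Cumulative Bass-diffusion adoption fraction at a given time.

    AR(t) = (1 - exp(-(P+Q) t)) / (1 + (Q/P) exp(-(P+Q) t)) with innovation
    rate P > 0 and imitation rate Q >= 0; 0 at t = 0, approaching 1 as t
    grows, non-decreasing in between.
    """
    if not innovation > 0:
        raise ValueError(f"innovation rate must be > 0, got {innovation}")
    if imitation < 0:
        raise ValueError(f"imitation rate must be >= 0, got {imitation}")
    if year < 0:
        raise ValueError(f"year must be >= 0, got {year}")
    e = math.exp(-(innovation + imitation) * year)
    return (1.0 - e) / (1.0 + (imitation / innovation) * e)


def _sample_categorical(
    probabilities: Sequence[float], rng: np.random.Generator
) -> int | None:
    """Sample a factor index or None (the residual no-risk state)."""
    if not probabilities:
        return None
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probabilities):
        acc += p
        if u < acc:
            return i
    return None


def sample_risk_realization(
    spec: ProjectSpec,
    scenario: ScenarioSpec | None,
    rng: np.random.Generator,
) -> RiskRealization:
    """Sample risk states: adoption/financial once, natural per year.

    Each category is multinomial over its factors plus the implicit
    none-state (probability 1 - sum).  Categories deactivated by the
    scenario always realize the none-state.
    """
    if scenario is not None:
        spec = apply_scenario(spec, scenario)
    adoption_ps = [r.probability for r in spec.adoption_risks]
    financial_ps = [r.probability for r in spec.financial_risks]
    natural_ps = [r.annual_probability for r in spec.natural_risks]
    return RiskRealization(
        adoption_state=_sample_categorical(adoption_ps, rng),
        financial_state=_sample_categorical(financial_ps, rng),
        natural_states=tuple(
            _sample_categorical(natural_ps, rng)
            for _ in range(spec.evaluation_period)
        ),
    )


class _ClampCounter:
    """Counts negative samples clamped to zero within one draw."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def clamp(self, x: float) -> float:
        if x < 0.0:
            self.count += 1
            return 0.0
        return x


def simulate_draw(
    spec: ProjectSpec,
    scenario: ScenarioSpec | None,
    rng: np.random.Generator,
    _clamp: _ClampCounter | None = None,
) -> DrawTrajectory:
    """One coherent draw of the full value chain.

    Per year t (1-based in the formulas below):

    * adopters         B_t  = AR_t * TB
    * productivity     PR_t = IP * EP_t - IB * EB_t
    * impact           I_t  = B_t * (PR_t + CL),  CL = GHGB * GHGC
    * budget flag      REB_t = 1 if cumulative cost exceeds the budget
    * adjusted impact  IA_t = REB_t * I_t * RR + (1 - REB_t) * I_t
    * disc. benefit    R_t  = (IA_t - C_t) / (1 + d)^t

    NPV = sum_t R_t; ROI = NPV / total (optionally discounted) cost.
    Costs keep accruing after budget exhaustion; only impact is penalized.
    Negative sampled monetary quantities are clamped at 0 and counted.
    """
    if scenario is not None:
        spec = apply_scenario(spec, scenario)
    m = spec.evaluation_period
    clamp = _clamp if _clamp is not None else _ClampCounter()

    risk = sample_risk_realization(spec, None, rng)
    adoption_factor = (
        spec.adoption_risks[risk.adoption_state]
        if risk.adoption_state is not None else None)
    financial_factor = (
        spec.financial_risks[risk.financial_state]
        if risk.financial_state is not None else None)

    # --- lifetime quantities -------------------------------------------
    pool = clamp.clamp(float(spec.adoption.target_pool.sample(rng)))
    if adoption_factor is not None and adoption_factor.beneficiary_pool_effect is not None:
        pool = clamp.clamp(adoption_factor.beneficiary_pool_effect.realize(pool, rng))

    ib = clamp.clamp(float(spec.impact.baseline_income.sample(rng)))
    if spec.impact.adopter_income is not None:
        ip = clamp.clamp(float(spec.impact.adopter_income.sample(rng)))
    else:
        ri = float(spec.impact.relative_impact.sample(rng))
        ip = clamp.clamp(ib * ri)
    climate = (float(spec.impact.ghg_balance.sample(rng))
               * float(spec.impact.ghg_cost.sample(rng)))

    budget = clamp.clamp(float(spec.finance.budget.sample(rng)))
    if financial_factor is not None:
        budget = clamp.clamp(financial_factor.budget_under_risk.realize(budget, rng))

    rate_multiplier = 1.0
    rate_conditionals: tuple[DistributionSpec, ...] | None = None
    if spec.adoption.mode == "bass":
        p_rate = float(spec.adoption.innovation_rate.sample(rng))
        q_rate = float(spec.adoption.imitation_rate.sample(rng))
        if adoption_factor is not None:
            if adoption_factor.bass_innovation_effect is not None:
                p_rate = adoption_factor.bass_innovation_effect.realize(p_rate, rng)
            if adoption_factor.bass_imitation_effect is not None:
                q_rate = adoption_factor.bass_imitation_effect.realize(q_rate, rng)
    elif adoption_factor is not None and adoption_factor.adoption_rate_effect is not None:
        eff = adoption_factor.adoption_rate_effect
        if isinstance(eff, tuple):
            rate_conditionals = eff
        elif eff.relative:
            # lifetime condition: one multiplier draw applied to every year
            rate_multiplier = float(eff.distribution.sample(rng))
        else:
            rate_conditionals = (eff.distribution,) * m

    # --- per-year quantities -------------------------------------------
    ar, adopters, ep, eb, pr, impact = [], [], [], [], [], []
    costs, reb, ia, benefit = [], [], [], []
    cumulative_cost = 0.0
    over = 0
    d = spec.finance.discount_rate
    rr = spec.finance.reduction_rate

    for t in range(m):
        if spec.adoption.mode == "bass":
            ar_t = adoption_rate_bass(p_rate, q_rate, t + 1)
        elif rate_conditionals is not None:
            ar_t = float(rate_conditionals[t].sample(rng))
        else:
            ar_t = float(spec.adoption.yearly_rates[t].sample(rng)) * rate_multiplier
        ar_t = min(max(ar_t, 0.0), 1.0)

        state = risk.natural_states[t]
        if state is None:
            ep_t = eb_t = 1.0
        else:
            factor = spec.natural_risks[state]
            ep_t = clamp.clamp(float(factor.beneficiary_income_multiplier.sample(rng)))
            eb_t = clamp.clamp(float(factor.baseline_income_multiplier.sample(rng)))

        b_t = ar_t * pool
        pr_t = ip * ep_t - ib * eb_t
        i_t = b_t * (pr_t + climate)
        c_t = clamp.clamp(float(spec.finance.yearly_costs[t].sample(rng)))
        cumulative_cost += c_t
        if cumulative_cost - budget > 0:
            over = 1
        ia_t = i_t * rr if over else i_t
        r_t = (ia_t - c_t) / (1.0 + d) ** (t + 1)

        ar.append(ar_t); adopters.append(b_t); ep.append(ep_t); eb.append(eb_t)
        pr.append(pr_t); impact.append(i_t); costs.append(c_t); reb.append(over)
        ia.append(ia_t); benefit.append(r_t)

    npv = float(sum(benefit))
    if spec.finance.roi_denominator == "discounted":
        denom = sum(c / (1.0 + d) ** (t + 1) for t, c in enumerate(costs))
    else:
        denom = sum(costs)
    if denom > 0:
        roi, roi_defined = npv / denom, True
    else:
        roi, roi_defined = math.nan, False

    return DrawTrajectory(
        adoption_fraction=tuple(ar),
        adopters=tuple(adopters),
        beneficiary_multiplier=tuple(ep),
        baseline_multiplier=tuple(eb),
        productivity_impact=tuple(pr),
        impact=tuple(impact),
        cost=tuple(costs),
        over_budget_flag=tuple(reb),
        adjusted_impact=tuple(ia),
        discounted_benefit=tuple(benefit),
        climate_impact=climate,
        realized_pool=pool,
        realized_budget=budget,
        npv=npv,
        roi=roi,
        roi_defined=roi_defined,
        risk=risk,
    )


def run_monte_carlo(
    spec: ProjectSpec,
    scenario: ScenarioSpec | None,
    n: int,
    seed: int,
) -> SimulationResult:
    """Draw ``n`` independent trajectories.

    Each draw uses its own child stream spawned deterministically from the
    root seed, so results are bit-identical across reruns and independent of
    n (the first k draws are the same whether n = k or n > k).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if scenario is not None:
        spec = apply_scenario(spec, scenario)
    violations = validate_project_spec(spec)
    if violations:
        raise SpecValidationError(violations)

    clamp = _ClampCounter()
    children = np.random.SeedSequence(seed).spawn(n)
    draws = [
        simulate_draw(spec, None, np.random.default_rng(child), _clamp=clamp)
        for child in children
    ]
    if clamp.count:
        logger.info("clamped %d negative samples to 0 across %d draws", clamp.count, n)
    return SimulationResult(
        draws=draws,
        n=n,
        seed=seed,
        scenario_name=scenario.name if scenario is not None else "All Risks",
        clamped_negative_draws=clamp.count,
    )


def condition_result(
    result: SimulationResult,
    predicate: Callable[[DrawTrajectory], bool],
) -> SimulationResult:
    """Filter a simulation down to the draws satisfying a predicate.

    This is a posteriori (rejection) conditioning of forward draws: the
    returned sub-population approximates the conditional distribution given
    the predicate, enabling backward queries such as the risk-state
    distribution given NPV < 0.
    """
    if not result.draws:
        raise EmptyConditionalError("cannot condition an empty simulation")
    weights = result.effective_weights()
    kept = [(d, w) for d, w in zip(result.draws, weights) if predicate(d)]
    if not kept:
        raise EmptyConditionalError(
            "no draw satisfies the predicate; rerun with a larger n")
    draws = [d for d, _ in kept]
    w = np.array([wt for _, wt in kept], dtype=float)
    return SimulationResult(
        draws=draws,
        n=len(draws),
        seed=result.seed,
        scenario_name=f"{result.scenario_name} | conditioned",
        weights=w / w.sum() * len(draws),
        clamped_negative_draws=result.clamped_negative_draws,
    )
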