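"""What-if risk scenarios.

A scenario switches whole risk categories on or off and optionally overrides
individual factor probabilities, producing a modified project spec for the
engine.  The standard four-scenario battery (no risks / natural only /
adoption & financial only / all risks) is the usual comparison grid for
judging a project's resilience.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .model_config import ProjectSpec

__all__ = ["ScenarioSpec", "standard_scenarios", "apply_scenario", "ALL_RISKS"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Activation flags per risk category plus per-factor probability
    overrides (applied after the flags, for single-factor what-ifs)."""

    name: str
    natural_active: bool = True
    adoption_active: bool = True
    financial_active: bool = True
    overrides: Mapping[str, float] = field(default_factory=dict)


ALL_RISKS = ScenarioSpec("All Risks")


def standard_scenarios() -> list[ScenarioSpec]:
    """The four standard what-if scenarios, ordered from risk-free to full."""
    return [
        ScenarioSpec("No Risks", natural_active=False, adoption_active=False,
                     financial_active=False),
        ScenarioSpec("Natural Risks Only", natural_active=True, adoption_active=False,
                     financial_active=False),
        ScenarioSpec("Adoption and Financial Risks Only", natural_active=False,
                     adoption_active=True, financial_active=True),
        ScenarioSpec("All Risks"),
    ]


def apply_scenario(spec: ProjectSpec, scenario: ScenarioSpec) -> ProjectSpec:
    """Return a new spec with the scenario applied; the input is unmodified.

    Deactivated categories get all factor probabilities set to 0 (the
    implicit none-state then has probability 1); overrides are applied last
    and must name existing factors.
    """
    for name, p in scenario.overrides.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"override for {name!r} must be in [0,1], got {p}")

    names = {r.name for r in spec.natural_risks}
    names |= {r.name for r in spec.adoption_risks}
    names |= {r.name for r in spec.financial_risks}
    missing = set(scenario.overrides) - names
    if missing:
        raise ValueError(f"scenario overrides name unknown factors: {sorted(missing)}")

    def prob(name: str, current: float, active: bool) -> float:
        p = current if active else 0.0
        return scenario.overrides.get(name, p)

    natural = tuple(
        replace(r, annual_probability=prob(r.name, r.annual_probability,
                                           scenario.natural_active))
        for r in spec.natural_risks)
    adoption = tuple(
        replace(r, probability=prob(r.name, r.probability, scenario.adoption_active))
        for r in spec.adoption_risks)
    financial = tuple(
        replace(r, probability=prob(r.name, r.probability, scenario.financial_active))
        for r in spec.financial_risks)
    return spec.replace(natural_risks=natural, adoption_risks=adoption,
                        financial_risks=financial)
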