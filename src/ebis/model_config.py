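"""Domain types and the project-specification schema.

A project specification describes everything the simulation engine needs:
finance (budget, yearly costs, discount rate), adoption (target pool and
uptake path, either directly elicited yearly rates or a Bass diffusion
curve), impact (incomes and greenhouse-gas terms) and the three risk-factor
categories (natural, adoption, financial).

Specifications are plain YAML documents.  All probabilities are fractions in
[0, 1], never percent; monetary amounts are USD as plain numbers.  Each risk
category implicitly contains a "none" state with probability
``1 - sum(factor probabilities)``; specs never list it explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

SCHEMA_VERSION = 1

FAMILIES = ("point", "uniform", "normal", "beta", "discrete")

__all__ = [
    "SCHEMA_VERSION",
    "DistributionSpec",
    "EffectSpec",
    "NaturalRiskFactor",
    "AdoptionRiskFactor",
    "FinancialRiskFactor",
    "AdoptionSpec",
    "ImpactSpec",
    "FinanceSpec",
    "ProjectSpec",
    "Violation",
    "SpecValidationError",
    "SchemaError",
    "validate_project_spec",
    "load_project_spec",
    "save_project_spec",
    "project_spec_from_dict",
    "project_spec_to_dict",
]


class SchemaError(ValueError):
    """Raised when a document cannot be interpreted as a project spec."""


@dataclass(frozen=True)
class Violation:
    """A single invariant violation, as data rather than an exception."""

    field: str
    rule: str
    message: str

    def to_dict(self) -> dict[str, str]:
        return {"field": self.field, "rule": self.rule, "message": self.message}


class SpecValidationError(ValueError):
    """Aggregated validation failure raised by :func:`load_project_spec`."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        lines = [f"  {v.field}: {v.rule} — {v.message}" for v in self.violations]
        super().__init__("project spec failed validation:\n" + "\n".join(lines))


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of a univariate prior.

    Families and parameters:

    ``point``     ``value``
    ``uniform``   ``low``, ``high``
    ``normal``    ``mean``, ``sd``
    ``beta``      ``alpha``, ``beta``; optional ``low``/``high`` rescale the
                  support from [0, 1] to [low, high]
    ``discrete``  ``values`` and ``probabilities`` of equal length

    ``units`` is a free-text tag (``USD``, ``fraction``, ``t CO2-eq`` ...)
    carried through for reporting; it does not affect sampling.
    """

    family: str
    params: Mapping[str, Any]
    units: str = ""

    # -- constructors -------------------------------------------------------

    @staticmethod
    def point(value: float, units: str = "") -> "DistributionSpec":
        return DistributionSpec("point", {"value": float(value)}, units)

    @staticmethod
    def uniform(low: float, high: float, units: str = "") -> "DistributionSpec":
        return DistributionSpec("uniform", {"low": float(low), "high": float(high)}, units)

    @staticmethod
    def normal(mean: float, sd: float, units: str = "") -> "DistributionSpec":
        return DistributionSpec("normal", {"mean": float(mean), "sd": float(sd)}, units)

    @staticmethod
    def beta(
        alpha: float,
        beta: float,
        low: float | None = None,
        high: float | None = None,
        units: str = "",
    ) -> "DistributionSpec":
        params: dict[str, Any] = {"alpha": float(alpha), "beta": float(beta)}
        if low is not None or high is not None:
            params["low"] = float(0.0 if low is None else low)
            params["high"] = float(1.0 if high is None else high)
        return DistributionSpec("beta", params, units)

    @staticmethod
    def discrete(
        pairs: Iterable[tuple[float, float]], units: str = ""
    ) -> "DistributionSpec":
        values, probs = zip(*((float(v), float(p)) for v, p in pairs))
        return DistributionSpec(
            "discrete", {"values": list(values), "probabilities": list(probs)}, units
        )

    # -- behaviour ----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.family == "point":
            v = p["value"]
            return v if size is None else np.full(size, v)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.family == "beta":
            x = rng.beta(p["alpha"], p["beta"], size)
            lo, hi = p.get("low", 0.0), p.get("high", 1.0)
            return lo + (hi - lo) * x
        if self.family == "discrete":
            return rng.choice(p["values"], size=size, p=p["probabilities"])
        raise SchemaError(f"unknown distribution family {self.family!r}")

    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.family == "normal":
            return p["mean"]
        if self.family == "beta":
            m = p["alpha"] / (p["alpha"] + p["beta"])
            lo, hi = p.get("low", 0.0), p.get("high", 1.0)
            return lo + (hi - lo) * m
        if self.family == "discrete":
            return float(
                np.dot(p["values"], p["probabilities"])
            )
        raise SchemaError(f"unknown distribution family {self.family!r}")

    def cdf(self, x: float) -> float:
        p = self.params
        if self.family == "point":
            return float(x >= p["value"])
        if self.family == "uniform":
            return float(stats.uniform.cdf(x, p["low"], p["high"] - p["low"]))
        if self.family == "normal":
            return float(stats.norm.cdf(x, p["mean"], p["sd"]))
        if self.family == "beta":
            lo, hi = p.get("low", 0.0), p.get("high", 1.0)
            return float(stats.beta.cdf((x - lo) / (hi - lo), p["alpha"], p["beta"]))
        if self.family == "discrete":
            return float(
                sum(pr for v, pr in zip(p["values"], p["probabilities"]) if v <= x)
            )
        raise SchemaError(f"unknown distribution family {self.family!r}")

    def support(self) -> tuple[float, float]:
        """(lower, upper) bounds of the support; normal is unbounded."""
        p = self.params
        if self.family == "point":
            return p["value"], p["value"]
        if self.family == "uniform":
            return p["low"], p["high"]
        if self.family == "normal":
            return -math.inf, math.inf
        if self.family == "beta":
            return p.get("low", 0.0), p.get("high", 1.0)
        if self.family == "discrete":
            return min(p["values"]), max(p["values"])
        raise SchemaError(f"unknown distribution family {self.family!r}")

    def validate(self, where: str) -> list[Violation]:
        out: list[Violation] = []
        p = self.params
        if self.family not in FAMILIES:
            return [Violation(where, "family", f"unknown family {self.family!r}")]
        required = {
            "point": ("value",),
            "uniform": ("low", "high"),
            "normal": ("mean", "sd"),
            "beta": ("alpha", "beta"),
            "discrete": ("values", "probabilities"),
        }[self.family]
        missing = [k for k in required if k not in p]
        if missing:
            return [Violation(where, "params", f"missing parameters {missing}")]
        if self.family == "uniform" and not p["low"] < p["high"]:
            out.append(Violation(where, "low < high", f"low={p['low']} high={p['high']}"))
        if self.family == "normal" and not p["sd"] > 0:
            out.append(Violation(where, "sd > 0", f"sd={p['sd']}"))
        if self.family == "beta":
            if not (p["alpha"] > 0 and p["beta"] > 0):
                out.append(
                    Violation(where, "alpha > 0 and beta > 0",
                              f"alpha={p['alpha']} beta={p['beta']}")
                )
            if "low" in p and not p["low"] < p["high"]:
                out.append(Violation(where, "low < high", f"scale bounds {p['low']}..{p['high']}"))
        if self.family == "discrete":
            probs = p["probabilities"]
            if len(probs) != len(p["values"]) or not probs:
                out.append(Violation(where, "values/probabilities", "length mismatch or empty"))
            else:
                if any(not 0.0 <= q <= 1.0 for q in probs):
                    out.append(Violation(where, "probabilities in [0,1]", str(probs)))
                if abs(sum(probs) - 1.0) > 1e-9:
                    out.append(Violation(where, "probabilities sum to 1", f"sum={sum(probs)}"))
        return out

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"family": self.family, **dict(self.params)}
        if self.units:
            d["units"] = self.units
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str = "distribution") -> "DistributionSpec":
        if not isinstance(d, Mapping) or "family" not in d:
            raise SchemaError(f"{where}: expected a mapping with a 'family' key, got {d!r}")
        d = dict(d)
        family = d.pop("family")
        units = d.pop("units", "")
        return DistributionSpec(family, d, units)


def _nonneg_support(dist: DistributionSpec, where: str, rule: str) -> list[Violation]:
    # normal has unbounded support; negative tail is clamped at sampling time
    lo, _ = dist.support()
    if lo < 0 and not math.isinf(lo):
        return [Violation(where, rule, f"support lower bound {lo} < 0")]
    return []


# ---------------------------------------------------------------------------
# Risk-effect shorthand
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """A risk effect: either a full conditional distribution for the affected
    quantity (``relative=False``) or a multiplier distribution applied to the
    baseline draw (``relative=True``).

    The multiplier shorthand exists because effects are commonly elicited as
    fractional changes ("a 15%–25% decrease" becomes a uniform(0.75, 0.85)
    multiplier).
    """

    distribution: DistributionSpec
    relative: bool = True

    def realize(self, baseline: float, rng: np.random.Generator) -> float:
        draw = float(self.distribution.sample(rng))
        return baseline * draw if self.relative else draw

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": "multiplier" if self.relative else "absolute",
            **self.distribution.to_dict(),
        }

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str = "effect") -> "EffectSpec":
        if not isinstance(d, Mapping) or "kind" not in d:
            raise SchemaError(f"{where}: expected a mapping with a 'kind' key")
        d = dict(d)
        kind = d.pop("kind")
        if kind not in ("multiplier", "absolute"):
            raise SchemaError(f"{where}.kind: expected 'multiplier' or 'absolute', got {kind!r}")
        return EffectSpec(DistributionSpec.from_dict(d, where), relative=(kind == "multiplier"))

    def validate(self, where: str) -> list[Violation]:
        return self.distribution.validate(where)


# ---------------------------------------------------------------------------
# Risk factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NaturalRiskFactor:
    """A hazard (drought, flood, pest outbreak ...) that may occur in any
    project year and scales that year's incomes.

    The two multiplier distributions are retained-income fractions: the share
    of yearly income kept when the hazard strikes, for project beneficiaries
    and for non-adopters respectively.
    """

    name: str
    annual_probability: float
    beneficiary_income_multiplier: DistributionSpec
    baseline_income_multiplier: DistributionSpec

    def validate(self, where: str) -> list[Violation]:
        out: list[Violation] = []
        if not 0.0 <= self.annual_probability <= 1.0:
            out.append(Violation(f"{where}.annual_probability", "in [0,1]",
                                 str(self.annual_probability)))
        for tag, dist in (
            ("beneficiary_income_multiplier", self.beneficiary_income_multiplier),
            ("baseline_income_multiplier", self.baseline_income_multiplier),
        ):
            out += dist.validate(f"{where}.{tag}")
            out += _nonneg_support(dist, f"{where}.{tag}", "non-negative support")
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "annual_probability": self.annual_probability,
            "beneficiary_income_multiplier": self.beneficiary_income_multiplier.to_dict(),
            "baseline_income_multiplier": self.baseline_income_multiplier.to_dict(),
        }

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str) -> "NaturalRiskFactor":
        try:
            return NaturalRiskFactor(
                name=str(d["name"]),
                annual_probability=float(d["annual_probability"]),
                beneficiary_income_multiplier=DistributionSpec.from_dict(
                    d["beneficiary_income_multiplier"],
                    f"{where}.beneficiary_income_multiplier"),
                baseline_income_multiplier=DistributionSpec.from_dict(
                    d["baseline_income_multiplier"], f"{where}.baseline_income_multiplier"),
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e


@dataclass(frozen=True)
class AdoptionRiskFactor:
    """A socio-political condition (political crisis, conflict, poor
    governance) realized once per project lifetime that depresses adoption.

    Effect channels (at least one must be set):

    * ``adoption_rate_effect`` — a per-year list of conditional adoption-rate
      distributions, or a single multiplier applied to the baseline rates;
    * ``beneficiary_pool_effect`` — conditional distribution or multiplier
      for the target pool;
    * ``bass_innovation_effect`` / ``bass_imitation_effect`` — conditional
      Bass-curve parameters (only meaningful in bass adoption mode).
    """

    name: str
    probability: float
    adoption_rate_effect: EffectSpec | tuple[DistributionSpec, ...] | None = None
    beneficiary_pool_effect: EffectSpec | None = None
    bass_innovation_effect: EffectSpec | None = None
    bass_imitation_effect: EffectSpec | None = None

    def validate(self, where: str, m: int | None = None) -> list[Violation]:
        out: list[Violation] = []
        if not 0.0 <= self.probability <= 1.0:
            out.append(Violation(f"{where}.probability", "in [0,1]", str(self.probability)))
        channels = (self.adoption_rate_effect, self.beneficiary_pool_effect,
                    self.bass_innovation_effect, self.bass_imitation_effect)
        if all(c is None for c in channels):
            out.append(Violation(where, "at least one effect channel", "no effects defined"))
        eff = self.adoption_rate_effect
        if isinstance(eff, tuple):
            if m is not None and len(eff) != m:
                out.append(Violation(f"{where}.adoption_rate_effect",
                                     "per-year list length equals m",
                                     f"{len(eff)} entries for m={m}"))
            for t, dist in enumerate(eff):
                out += dist.validate(f"{where}.adoption_rate_effect[{t}]")
        elif eff is not None:
            out += eff.validate(f"{where}.adoption_rate_effect")
        for tag in ("beneficiary_pool_effect", "bass_innovation_effect",
                    "bass_imitation_effect"):
            e = getattr(self, tag)
            if e is not None:
                out += e.validate(f"{where}.{tag}")
        return out

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"name": self.name, "probability": self.probability}
        eff = self.adoption_rate_effect
        if isinstance(eff, tuple):
            d["adoption_rate_effect"] = {
                "kind": "per_year",
                "distributions": [x.to_dict() for x in eff],
            }
        elif eff is not None:
            d["adoption_rate_effect"] = eff.to_dict()
        for tag in ("beneficiary_pool_effect", "bass_innovation_effect",
                    "bass_imitation_effect"):
            e = getattr(self, tag)
            if e is not None:
                d[tag] = e.to_dict()
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str) -> "AdoptionRiskFactor":
        try:
            name = str(d["name"])
            probability = float(d["probability"])
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e
        rate_eff: EffectSpec | tuple[DistributionSpec, ...] | None = None
        raw = d.get("adoption_rate_effect")
        if raw is not None:
            if isinstance(raw, Mapping) and raw.get("kind") == "per_year":
                rate_eff = tuple(
                    DistributionSpec.from_dict(x, f"{where}.adoption_rate_effect[{i}]")
                    for i, x in enumerate(raw["distributions"])
                )
            else:
                rate_eff = EffectSpec.from_dict(raw, f"{where}.adoption_rate_effect")
        kwargs = {}
        for tag in ("beneficiary_pool_effect", "bass_innovation_effect",
                    "bass_imitation_effect"):
            if d.get(tag) is not None:
                kwargs[tag] = EffectSpec.from_dict(d[tag], f"{where}.{tag}")
        return AdoptionRiskFactor(name=name, probability=probability,
                                  adoption_rate_effect=rate_eff, **kwargs)


@dataclass(frozen=True)
class FinancialRiskFactor:
    """A funding condition realized once per project lifetime that changes
    the available budget (conditional distribution or multiplier)."""

    name: str
    probability: float
    budget_under_risk: EffectSpec

    def validate(self, where: str) -> list[Violation]:
        out: list[Violation] = []
        if not 0.0 <= self.probability <= 1.0:
            out.append(Violation(f"{where}.probability", "in [0,1]", str(self.probability)))
        out += self.budget_under_risk.validate(f"{where}.budget_under_risk")
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "probability": self.probability,
            "budget_under_risk": self.budget_under_risk.to_dict(),
        }

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str) -> "FinancialRiskFactor":
        try:
            return FinancialRiskFactor(
                name=str(d["name"]),
                probability=float(d["probability"]),
                budget_under_risk=EffectSpec.from_dict(
                    d["budget_under_risk"], f"{where}.budget_under_risk"),
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e


# ---------------------------------------------------------------------------
# Component specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdoptionSpec:
    """How the target pool takes up the project over time.

    ``mode='direct'`` uses elicited cumulative adoption fractions per year
    (``yearly_rates``, one distribution per year); ``mode='bass'`` uses the
    two-parameter Bass diffusion curve (``innovation_rate`` P and
    ``imitation_rate`` Q).  ``scope_basis`` records whether the pool counts
    beneficiaries (persons) or farming area (hectares); the arithmetic is
    identical.
    """

    mode: str  # direct | bass
    target_pool: DistributionSpec
    scope_basis: str = "beneficiaries"  # beneficiaries | area
    yearly_rates: tuple[DistributionSpec, ...] | None = None
    innovation_rate: DistributionSpec | None = None
    imitation_rate: DistributionSpec | None = None

    def validate(self, where: str, m: int) -> list[Violation]:
        out: list[Violation] = []
        if self.mode not in ("direct", "bass"):
            out.append(Violation(f"{where}.mode", "direct|bass", repr(self.mode)))
        if self.scope_basis not in ("beneficiaries", "area"):
            out.append(Violation(f"{where}.scope_basis", "beneficiaries|area",
                                 repr(self.scope_basis)))
        out += self.target_pool.validate(f"{where}.target_pool")
        if self.mode == "direct":
            if self.yearly_rates is None:
                out.append(Violation(f"{where}.yearly_rates", "required in direct mode",
                                     "missing"))
            else:
                if len(self.yearly_rates) != m:
                    out.append(Violation(f"{where}.yearly_rates", "length equals m",
                                         f"{len(self.yearly_rates)} entries for m={m}"))
                for t, dist in enumerate(self.yearly_rates):
                    w = f"{where}.yearly_rates[{t}]"
                    out += dist.validate(w)
                    lo, hi = dist.support()
                    if not math.isinf(lo) and (lo < 0 or hi > 1):
                        out.append(Violation(w, "support in [0,1]", f"support [{lo}, {hi}]"))
        if self.mode == "bass":
            if self.innovation_rate is None or self.imitation_rate is None:
                out.append(Violation(f"{where}", "bass mode needs innovation and imitation rates",
                                     "missing"))
            else:
                out += self.innovation_rate.validate(f"{where}.innovation_rate")
                out += self.imitation_rate.validate(f"{where}.imitation_rate")
        return out

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "mode": self.mode,
            "scope_basis": self.scope_basis,
            "target_pool": self.target_pool.to_dict(),
        }
        if self.yearly_rates is not None:
            d["yearly_rates"] = [x.to_dict() for x in self.yearly_rates]
        if self.innovation_rate is not None:
            d["innovation_rate"] = self.innovation_rate.to_dict()
        if self.imitation_rate is not None:
            d["imitation_rate"] = self.imitation_rate.to_dict()
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str = "adoption") -> "AdoptionSpec":
        try:
            mode = str(d["mode"])
            pool = DistributionSpec.from_dict(d["target_pool"], f"{where}.target_pool")
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e
        rates = d.get("yearly_rates")
        return AdoptionSpec(
            mode=mode,
            scope_basis=str(d.get("scope_basis", "beneficiaries")),
            target_pool=pool,
            yearly_rates=(
                tuple(DistributionSpec.from_dict(x, f"{where}.yearly_rates[{i}]")
                      for i, x in enumerate(rates))
                if rates is not None else None),
            innovation_rate=(DistributionSpec.from_dict(d["innovation_rate"],
                                                        f"{where}.innovation_rate")
                             if d.get("innovation_rate") is not None else None),
            imitation_rate=(DistributionSpec.from_dict(d["imitation_rate"],
                                                       f"{where}.imitation_rate")
                            if d.get("imitation_rate") is not None else None),
        )


@dataclass(frozen=True)
class ImpactSpec:
    """Productivity and climate impact terms.

    Per-beneficiary productivity impact is the income difference between an
    adopter and a non-adopter; the adopter income is either elicited directly
    (``adopter_income``) or derived as baseline × ``relative_impact``
    (exactly one of the two must be set).  Climate impact per beneficiary is
    ``ghg_balance × ghg_cost``.
    """

    baseline_income: DistributionSpec
    ghg_balance: DistributionSpec
    ghg_cost: DistributionSpec
    adopter_income: DistributionSpec | None = None
    relative_impact: DistributionSpec | None = None

    def validate(self, where: str) -> list[Violation]:
        out: list[Violation] = []
        if (self.adopter_income is None) == (self.relative_impact is None):
            out.append(Violation(where, "exactly one of adopter_income/relative_impact",
                                 "both set" if self.adopter_income is not None
                                 else "neither set"))
        out += self.baseline_income.validate(f"{where}.baseline_income")
        out += self.ghg_balance.validate(f"{where}.ghg_balance")
        out += self.ghg_cost.validate(f"{where}.ghg_cost")
        if self.adopter_income is not None:
            out += self.adopter_income.validate(f"{where}.adopter_income")
        if self.relative_impact is not None:
            out += self.relative_impact.validate(f"{where}.relative_impact")
        return out

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "baseline_income": self.baseline_income.to_dict(),
            "ghg_balance": self.ghg_balance.to_dict(),
            "ghg_cost": self.ghg_cost.to_dict(),
        }
        if self.adopter_income is not None:
            d["adopter_income"] = self.adopter_income.to_dict()
        if self.relative_impact is not None:
            d["relative_impact"] = self.relative_impact.to_dict()
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str = "impact") -> "ImpactSpec":
        try:
            return ImpactSpec(
                baseline_income=DistributionSpec.from_dict(
                    d["baseline_income"], f"{where}.baseline_income"),
                ghg_balance=DistributionSpec.from_dict(d["ghg_balance"], f"{where}.ghg_balance"),
                ghg_cost=DistributionSpec.from_dict(d["ghg_cost"], f"{where}.ghg_cost"),
                adopter_income=(DistributionSpec.from_dict(d["adopter_income"],
                                                           f"{where}.adopter_income")
                                if d.get("adopter_income") is not None else None),
                relative_impact=(DistributionSpec.from_dict(d["relative_impact"],
                                                            f"{where}.relative_impact")
                                 if d.get("relative_impact") is not None else None),
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e


@dataclass(frozen=True)
class FinanceSpec:
    """Budget, yearly costs, discounting and budget-overrun penalty.

    ``reduction_rate`` (RR) is the fraction of yearly impact retained once
    cumulative cost exceeds the budget.  ``roi_denominator`` selects whether
    ROI divides NPV by the plain or the discounted total cost.
    """

    budget: DistributionSpec
    yearly_costs: tuple[DistributionSpec, ...]
    discount_rate: float
    reduction_rate: float = 0.5
    roi_denominator: str = "undiscounted"  # undiscounted | discounted

    def validate(self, where: str, m: int) -> list[Violation]:
        out: list[Violation] = []
        out += self.budget.validate(f"{where}.budget")
        if len(self.yearly_costs) != m:
            out.append(Violation(f"{where}.yearly_costs", "length equals m",
                                 f"{len(self.yearly_costs)} entries for m={m}"))
        for t, dist in enumerate(self.yearly_costs):
            w = f"{where}.yearly_costs[{t}]"
            out += dist.validate(w)
            out += _nonneg_support(dist, w, "non-negative support")
        if not self.discount_rate >= 0:
            out.append(Violation(f"{where}.discount_rate", ">= 0", str(self.discount_rate)))
        if not 0.0 <= self.reduction_rate <= 1.0:
            out.append(Violation(f"{where}.reduction_rate", "in [0,1]",
                                 str(self.reduction_rate)))
        if self.roi_denominator not in ("undiscounted", "discounted"):
            out.append(Violation(f"{where}.roi_denominator", "undiscounted|discounted",
                                 repr(self.roi_denominator)))
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "budget": self.budget.to_dict(),
            "yearly_costs": [c.to_dict() for c in self.yearly_costs],
            "discount_rate": self.discount_rate,
            "reduction_rate": self.reduction_rate,
            "roi_denominator": self.roi_denominator,
        }

    @staticmethod
    def from_dict(d: Mapping[str, Any], where: str = "finance") -> "FinanceSpec":
        try:
            return FinanceSpec(
                budget=DistributionSpec.from_dict(d["budget"], f"{where}.budget"),
                yearly_costs=tuple(
                    DistributionSpec.from_dict(x, f"{where}.yearly_costs[{i}]")
                    for i, x in enumerate(d["yearly_costs"])),
                discount_rate=float(d["discount_rate"]),
                reduction_rate=float(d.get("reduction_rate", 0.5)),
                roi_denominator=str(d.get("roi_denominator", "undiscounted")),
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e


@dataclass(frozen=True)
class ProjectSpec:
    """Full model parameterization for one investment project."""

    name: str
    evaluation_period: int
    finance: FinanceSpec
    adoption: AdoptionSpec
    impact: ImpactSpec
    natural_risks: tuple[NaturalRiskFactor, ...] = ()
    adoption_risks: tuple[AdoptionRiskFactor, ...] = ()
    financial_risks: tuple[FinancialRiskFactor, ...] = ()

    def replace(self, **changes: Any) -> "ProjectSpec":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "evaluation_period": self.evaluation_period,
            "finance": self.finance.to_dict(),
            "adoption": self.adoption.to_dict(),
            "impact": self.impact.to_dict(),
            "natural_risks": [r.to_dict() for r in self.natural_risks],
            "adoption_risks": [r.to_dict() for r in self.adoption_risks],
            "financial_risks": [r.to_dict() for r in self.financial_risks],
        }


def project_spec_from_dict(d: Mapping[str, Any]) -> ProjectSpec:
    if not isinstance(d, Mapping):
        raise SchemaError(f"top level: expected a mapping, got {type(d).__name__}")
    version = d.get("schema_version", SCHEMA_VERSION)
    if int(version) != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: unsupported version {version}")
    try:
        name = str(d["name"])
        m = int(d["evaluation_period"])
        finance = FinanceSpec.from_dict(d["finance"])
        adoption = AdoptionSpec.from_dict(d["adoption"])
        impact = ImpactSpec.from_dict(d["impact"])
    except KeyError as e:
        raise SchemaError(f"top level: missing key {e.args[0]!r}") from e
    return ProjectSpec(
        name=name,
        evaluation_period=m,
        finance=finance,
        adoption=adoption,
        impact=impact,
        natural_risks=tuple(
            NaturalRiskFactor.from_dict(x, f"natural_risks[{i}]")
            for i, x in enumerate(d.get("natural_risks", []) or [])),
        adoption_risks=tuple(
            AdoptionRiskFactor.from_dict(x, f"adoption_risks[{i}]")
            for i, x in enumerate(d.get("adoption_risks", []) or [])),
        financial_risks=tuple(
            FinancialRiskFactor.from_dict(x, f"financial_risks[{i}]")
            for i, x in enumerate(d.get("financial_risks", []) or [])),
    )


def project_spec_to_dict(spec: ProjectSpec) -> dict[str, Any]:
    return spec.to_dict()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_project_spec(spec: ProjectSpec) -> list[Violation]:
    """Check every invariant; returns an empty list iff the spec is valid.

    Violations are returned as data (field, rule, message) so callers can
    aggregate or export them; nothing is raised.
    """
    out: list[Violation] = []
    m = spec.evaluation_period
    if not (isinstance(m, int) and m >= 1):
        out.append(Violation("evaluation_period", "positive integer", str(m)))
        m = max(int(m), 1)
    out += spec.finance.validate("finance", m)
    out += spec.adoption.validate("adoption", m)
    out += spec.impact.validate("impact")
    for i, r in enumerate(spec.natural_risks):
        out += r.validate(f"natural_risks[{i}]")
    for i, r in enumerate(spec.adoption_risks):
        out += r.validate(f"adoption_risks[{i}]", m)
    for i, r in enumerate(spec.financial_risks):
        out += r.validate(f"financial_risks[{i}]")
    # each category plus its implicit none-state must form a distribution
    for tag, factors, key in (
        ("natural_risks", spec.natural_risks, "annual_probability"),
        ("adoption_risks", spec.adoption_risks, "probability"),
        ("financial_risks", spec.financial_risks, "probability"),
    ):
        total = sum(getattr(r, key) for r in factors)
        if total > 1.0 + 1e-9:
            out.append(Violation(tag, "category probability sum <= 1", f"sum={total}"))
    return out


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------


def load_project_spec(path) -> ProjectSpec:
    """Read and validate a YAML project specification.

    Raises :class:`SchemaError` on parse/structure failure (naming the
    offending key) and :class:`SpecValidationError` with the full violation
    list when the document parses but breaks an invariant.
    """
    with open(path, "r") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise SchemaError(f"{path}: not valid YAML: {e}") from e
    spec = project_spec_from_dict(raw)
    violations = validate_project_spec(spec)
    if violations:
        raise SpecValidationError(violations)
    return spec


def save_project_spec(spec: ProjectSpec, path) -> None:
    """Write a validated spec as YAML; ``load_project_spec`` inverts it."""
    violations = validate_project_spec(spec)
    if violations:
        raise SpecValidationError(violations)
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False, default_flow_style=False)
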