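"""Evidence-to-prior conversion utilities.

Expert estimates and published evidence rarely arrive as ready-made
probability distributions.  This module converts the common raw forms —
optimistic/pessimistic percentile pairs, historical event counts, governance
indicator scores, rainfall series, and lists of published effect sizes —
into :class:`~ebis.model_config.DistributionSpec` priors or probabilities
the engine can consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model_config import DistributionSpec

__all__ = [
    "EffectEstimate",
    "IndicatorScale",
    "ConvergenceError",
    "fit_normal_from_percentiles",
    "fit_beta_from_percentiles",
    "annual_prob_from_frequency",
    "prob_from_indicator_scale",
    "count_drought_events",
    "combine_likelihood_estimates",
    "pool_effect_estimates",
    "relative_to_absolute_income",
    "ProductDistribution",
]


class ConvergenceError(RuntimeError):
    """A numeric fit failed to reach the requested residual tolerance."""

    def __init__(self, message: str, residuals: Sequence[float] = ()):
        super().__init__(message)
        self.residuals = tuple(residuals)


@dataclass(frozen=True)
class EffectEstimate:
    """One published effect-size estimate (e.g. percent yield change) with
    its dispersion, as extracted from a study or evidence repository."""

    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class IndicatorScale:
    """Linear mapping from an indicator score to an event probability.

    ``score_at_certain`` maps to probability 1 and ``score_at_impossible``
    to probability 0; scores in between map linearly, scores outside are
    clamped.  Used for governance/conflict indicators (e.g. a political
    stability score of -3 meaning certain instability, 2 meaning none).
    """

    score_at_certain: float
    score_at_impossible: float

    def __post_init__(self):
        if self.score_at_certain == self.score_at_impossible:
            raise ValueError("degenerate scale: anchors must differ")

    @property
    def slope(self) -> float:
        return 1.0 / (self.score_at_impossible - self.score_at_certain)


def fit_normal_from_percentiles(
    low_value: float, high_value: float, p_low: float, p_high: float,
    units: str = "",
) -> DistributionSpec:
    """Fit a Normal prior from two elicited percentiles.

    Typical use: pessimistic and optimistic expert estimates interpreted as
    the 1st and 99th percentiles.  The fit is exact: with z the standard
    normal quantile function, sd = (high - low) / (z(p_high) - z(p_low)) and
    mean = low - z(p_low) * sd.
    """
    if not low_value < high_value:
        raise ValueError(f"low_value must be < high_value ({low_value} >= {high_value})")
    if not 0.0 < p_low < p_high < 1.0:
        raise ValueError(f"need 0 < p_low < p_high < 1, got ({p_low}, {p_high})")
    z_low = stats.norm.ppf(p_low)
    z_high = stats.norm.ppf(p_high)
    sd = (high_value - low_value) / (z_high - z_low)
    mean = low_value - z_low * sd
    return DistributionSpec.normal(mean, sd, units)


def fit_beta_from_percentiles(
    low_value: float, high_value: float, p_low: float, p_high: float,
    units: str = "fraction", tol: float = 1e-6, max_iter: int = 200,
) -> DistributionSpec:
    """Fit a Beta prior on [0, 1] matching two elicited percentiles.

    Solves numerically for (alpha, beta) such that the Beta CDF equals
    ``p_low`` at ``low_value`` and ``p_high`` at ``high_value``, to within
    ``tol``.  Suitable for fractions such as adoption rates.
    """
    if not 0.0 <= low_value < high_value <= 1.0:
        raise ValueError(
            f"need 0 <= low_value < high_value <= 1, got ({low_value}, {high_value})")
    if not 0.0 < p_low < p_high < 1.0:
        raise ValueError(f"need 0 < p_low < p_high < 1, got ({p_low}, {p_high})")

    def residual(log_params):
        a, b = np.exp(log_params)
        return [
            stats.beta.cdf(low_value, a, b) - p_low,
            stats.beta.cdf(high_value, a, b) - p_high,
        ]

    # moment-matched start: midpoint as mean, quarter-range as sd
    mid = 0.5 * (low_value + high_value)
    spread = max((high_value - low_value) / 4.0, 1e-3)
    var = spread**2
    common = mid * (1 - mid) / var - 1.0
    a0 = max(mid * common, 0.5)
    b0 = max((1 - mid) * common, 0.5)
    sol = optimize.root(residual, np.log([a0, b0]), method="hybr",
                        options={"maxfev": max_iter * 2})
    res = residual(sol.x)
    if max(abs(r) for r in res) > tol:
        raise ConvergenceError(
            f"beta percentile fit did not converge below {tol}", residuals=res)
    a, b = np.exp(sol.x)
    return DistributionSpec.beta(float(a), float(b), units=units)


def annual_prob_from_frequency(event_count: float, span_years: float) -> float:
    """Annual event probability from a historical count over a span.

    E.g. one drought per decade gives a 10% chance in any given year.  The
    ratio is capped at 1.
    """
    if span_years <= 0:
        raise ValueError(f"span_years must be > 0, got {span_years}")
    if event_count < 0:
        raise ValueError(f"event_count must be >= 0, got {event_count}")
    return min(event_count / span_years, 1.0)


def prob_from_indicator_scale(
    score_mean: float, score_sd: float, scale: IndicatorScale
) -> tuple[float, float]:
    """Map an indicator score (mean, sd) to an event probability (mean, sd).

    The mean maps affinely between the scale anchors and is clamped to
    [0, 1]; the sd scales by the absolute slope of the mapping.
    """
    if score_sd < 0:
        raise ValueError(f"score_sd must be >= 0, got {score_sd}")
    span = scale.score_at_impossible - scale.score_at_certain
    p = (scale.score_at_impossible - score_mean) / span
    p = min(max(p, 0.0), 1.0)
    return p, abs(scale.slope) * score_sd


def count_drought_events(monthly_rainfall: Sequence[float]) -> int:
    """Count drought events in a monthly rainfall series.

    A 12-month drought index is computed as the z-score of rolling 12-month
    rainfall totals against their own long-term mean and standard deviation.
    An event opens in a month where the index reaches -1 (one standard
    deviation below average) and closes when the index recovers to 0
    (average conditions); consecutive sub--1 months belong to one event, and
    an event still open at the end of the series counts once.

    Note this is the plain z-score reading of the 12-month standardized
    precipitation index, not the gamma-fitted SPI of the climatology
    literature (see docs/methods.md).
    """
    x = np.asarray(monthly_rainfall, dtype=float)
    if x.ndim != 1 or len(x) < 24:
        raise ValueError("need a 1-D series of at least 24 monthly values")
    totals = np.convolve(x, np.ones(12), mode="valid")  # rolling 12-month sums
    sd = totals.std(ddof=0)
    if sd == 0:
        # no variability at all: the index never departs from average
        # conditions, so no drought can open
        return 0
    z = (totals - totals.mean()) / sd
    events = 0
    in_event = False
    for value in z:
        if not in_event and value <= -1.0:
            in_event = True
            events += 1
        elif in_event and value >= 0.0:
            in_event = False
    return events


def combine_likelihood_estimates(
    values: Sequence[float], method: str = "mean"
) -> DistributionSpec:
    """Combine several annual-probability estimates into one prior.

    ``mean`` returns a point prior at the arithmetic mean; ``uniform_interval``
    returns a uniform prior over [min, max] (whose expectation is the
    midpoint).  With a single estimate both methods return a point prior.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("need at least one likelihood estimate")
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError(f"likelihoods must be in [0,1], got {vals}")
    if method not in ("mean", "uniform_interval"):
        raise ValueError(f"unknown method {method!r}")
    if method == "mean" or len(set(vals)) == 1:
        return DistributionSpec.point(float(np.mean(vals)), units="probability")
    return DistributionSpec.uniform(min(vals), max(vals), units="probability")


def pool_effect_estimates(
    estimates: Sequence[EffectEstimate], model: str = "random"
) -> EffectEstimate:
    """Meta-analytic pooling of effect estimates.

    ``fixed`` is the inverse-variance weighted mean with pooled standard
    error ``sqrt(1 / sum(w))``.  ``random`` adds the DerSimonian–Laird
    moment estimate of between-study variance tau^2 to each study variance
    before weighting, widening the pooled standard error when the estimates
    are heterogeneous.  A single estimate is returned unchanged.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    if len(estimates) == 1:
        return estimates[0]
    means = np.array([e.mean for e in estimates], dtype=float)
    variances = np.array([e.sd**2 for e in estimates], dtype=float)
    w = 1.0 / variances
    mu_fixed = float(np.sum(w * means) / np.sum(w))
    if model == "fixed":
        se = math.sqrt(1.0 / float(np.sum(w)))
        return EffectEstimate(mu_fixed, se, label="pooled (fixed)")
    q = float(np.sum(w * (means - mu_fixed) ** 2))
    df = len(estimates) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (variances + tau2)
    mu = float(np.sum(w_star * means) / np.sum(w_star))
    se = math.sqrt(1.0 / float(np.sum(w_star)))
    return EffectEstimate(mu, se, label="pooled (random, DL)")


@dataclass(frozen=True)
class ProductDistribution:
    """Derived quantity realized as the product of two independent draws.

    Used for adopter income when evidence gives a relative impact multiplier
    rather than an absolute income: income after adoption is baseline income
    times the relative impact, drawn independently.  For independent inputs
    the expectation of the product is the product of expectations.
    """

    baseline: DistributionSpec
    multiplier: DistributionSpec

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.baseline.sample(rng)) * float(self.multiplier.sample(rng))

    def mean(self) -> float:
        return self.baseline.mean() * self.multiplier.mean()


def relative_to_absolute_income(
    baseline: DistributionSpec, relative_impact: DistributionSpec
) -> ProductDistribution:
    """Descriptor for adopter income as baseline income × relative impact."""
    for dist, tag in ((baseline, "baseline"), (relative_impact, "relative_impact")):
        bad = dist.validate(tag)
        if bad:
            raise ValueError("; ".join(f"{v.field}: {v.rule}" for v in bad))
    return ProductDistribution(baseline, relative_impact)
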