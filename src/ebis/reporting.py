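"""Summaries, scenario-comparison tables and exports.

Produces the standard decision-support outputs: per-scenario mean/SD of NPV
and ROI, the probability of a positive NPV, NPV quantiles, and per-draw
distribution tables suitable for histogramming.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, run_monte_carlo
from .model_config import ProjectSpec
from .scenarios import ScenarioSpec

__all__ = [
    "DEFAULT_QUANTILE_LEVELS",
    "SummaryReport",
    "summarize",
    "compare_scenarios",
    "reports_to_frame",
    "export_report",
    "load_reports",
    "result_to_frame",
]

DEFAULT_QUANTILE_LEVELS = (0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)


@dataclass(frozen=True)
class SummaryReport:
    """Scenario-level statistics of a simulation.

    ``npv_sd``/``roi_sd`` are None when undefined (single draw).  ROI values
    are fractions; human-facing tables format them as percentages.
    """

    scenario_name: str
    npv_mean: float
    npv_sd: float | None
    roi_mean: float
    roi_sd: float | None
    prob_positive_npv: float
    quantiles: Mapping[float, float]
    n: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scenario_name": self.scenario_name,
            "npv_mean": self.npv_mean,
            "npv_sd": self.npv_sd,
            "roi_mean": self.roi_mean,
            "roi_sd": self.roi_sd,
            "prob_positive_npv": self.prob_positive_npv,
            "quantiles": {str(k): v for k, v in self.quantiles.items()},
            "n": self.n,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "SummaryReport":
        return SummaryReport(
            scenario_name=d["scenario_name"],
            npv_mean=d["npv_mean"],
            npv_sd=d["npv_sd"],
            roi_mean=d["roi_mean"],
            roi_sd=d["roi_sd"],
            prob_positive_npv=d["prob_positive_npv"],
            quantiles={float(k): v for k, v in d["quantiles"].items()},
            n=d["n"],
            seed=d["seed"],
        )


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float | None]:
    """Weighted mean and reliability-weighted sample SD (n-1 style).

    With uniform weights this reduces to the ordinary sample mean and the
    (n-1)-denominator sample standard deviation.  NaNs (undefined ROI
    draws) are excluded.
    """
    ok = ~np.isnan(x)
    x, w = x[ok], w[ok]
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    denom = wsum - np.sum(w**2) / wsum
    if denom <= 0:
        return mean, None
    var = float(np.sum(w * (x - mean) ** 2) / denom)
    return mean, math.sqrt(max(var, 0.0))


def _weighted_quantiles(
    x: np.ndarray, w: np.ndarray, levels: Sequence[float]
) -> dict[float, float]:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return {float(q): float(np.interp(q, cum, xs)) for q in levels}


def summarize(
    result: SimulationResult,
    quantile_levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> SummaryReport:
    """Weighted summary statistics of one simulation."""
    if not result.draws:
        raise ValueError("cannot summarize an empty simulation")
    npv = result.npv_values()
    roi = result.roi_values()
    w = result.effective_weights()
    npv_mean, npv_sd = _weighted_mean_sd(npv, w)
    roi_mean, roi_sd = _weighted_mean_sd(roi, w)
    prob_pos = float(np.sum(w[npv > 0]) / np.sum(w))
    return SummaryReport(
        scenario_name=result.scenario_name,
        npv_mean=npv_mean,
        npv_sd=npv_sd,
        roi_mean=roi_mean,
        roi_sd=roi_sd,
        prob_positive_npv=prob_pos,
        quantiles=_weighted_quantiles(npv, w, quantile_levels),
        n=len(result.draws),
        seed=result.seed,
    )


def compare_scenarios(
    spec: ProjectSpec,
    scenarios: Sequence[ScenarioSpec],
    n: int,
    seed: int,
    quantile_levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> list[SummaryReport]:
    """Simulate each scenario and summarize, in input order.

    Scenario i runs with seed ``seed + i`` (deterministic offset from the
    root seed), so the whole table is reproducible from one seed.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    return [
        summarize(run_monte_carlo(spec, sc, n, seed + i), quantile_levels)
        for i, sc in enumerate(scenarios)
    ]


def reports_to_frame(reports: Sequence[SummaryReport]) -> pd.DataFrame:
    """Comparison table, one row per scenario; ROI columns in percent."""
    rows = []
    for r in reports:
        row: dict = {
            "scenario": r.scenario_name,
            "npv_mean": r.npv_mean,
            "npv_sd": r.npv_sd,
            "roi_mean_pct": r.roi_mean * 100.0,
            "roi_sd_pct": r.roi_sd * 100.0 if r.roi_sd is not None else None,
            "prob_positive_npv": r.prob_positive_npv,
            "n": r.n,
            "seed": r.seed,
        }
        for q, v in sorted(r.quantiles.items()):
            row[f"npv_q{q:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def result_to_frame(result: SimulationResult, per_year: bool = False) -> pd.DataFrame:
    """One row per draw (NPV, ROI, risk states, weight), for histogramming.

    With ``per_year=True`` the per-year chains (adoption fraction, adopters,
    impact, cost, budget flag, discounted benefit) are added as
    ``<name>_y<t>`` columns.
    """
    w = result.effective_weights()
    rows = []
    for i, d in enumerate(result.draws):
        row: dict = {
            "draw": i,
            "npv": d.npv,
            "roi": d.roi,
            "roi_defined": d.roi_defined,
            "adoption_state": d.risk.adoption_state,
            "financial_state": d.risk.financial_state,
            "realized_pool": d.realized_pool,
            "realized_budget": d.realized_budget,
            "weight": w[i],
        }
        if per_year:
            for t in range(len(d.adoption_fraction)):
                row[f"adoption_fraction_y{t+1}"] = d.adoption_fraction[t]
                row[f"adopters_y{t+1}"] = d.adopters[t]
                row[f"impact_y{t+1}"] = d.impact[t]
                row[f"cost_y{t+1}"] = d.cost[t]
                row[f"over_budget_y{t+1}"] = d.over_budget_flag[t]
                row[f"discounted_benefit_y{t+1}"] = d.discounted_benefit[t]
                row[f"natural_state_y{t+1}"] = d.risk.natural_states[t]
        rows.append(row)
    return pd.DataFrame(rows)


def export_report(
    reports: Sequence[SummaryReport],
    result: SimulationResult | None,
    path,
    format: str = "csv",
) -> list[Path]:
    """Write the comparison table (and optionally the per-draw table).

    ``path`` is the summary file; a per-draw distribution file with suffix
    ``.draws.csv`` is written alongside it when ``result`` is given.
    Identical inputs yield byte-identical files.
    """
    if not reports:
        raise ValueError("need at least one report to export")
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    written = [path]
    try:
        if format == "csv":
            reports_to_frame(reports).to_csv(path, index=False)
        else:
            with open(path, "w") as fh:
                json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        if result is not None:
            draws_path = path.with_suffix(".draws.csv")
            result_to_frame(result).to_csv(draws_path, index=False)
            written.append(draws_path)
    except OSError as e:
        raise OSError(f"failed writing report to {path}: {e}") from e
    return written


def load_reports(path) -> list[SummaryReport]:
    """Read back a JSON report file written by :func:`export_report`."""
    with open(path) as fh:
        raw = json.load(fh)
    return [SummaryReport.from_dict(d) for d in raw]
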