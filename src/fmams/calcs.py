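"""Sample-size and event-rate arithmetic for factorial planning.

In a factorial trial an effective intervention in *another* randomisation
lowers the marginal event rate seen by a comparison, which erodes its power
at fixed sample size (event-rate dilution).  These helpers quantify that:
the diluted marginal control-group rate under a mixture of co-intervention
allocation cells, the standard two-proportion sample size on the diluted
rates, and the power curve across a grid of co-intervention effect sizes.

Dilution is computed exactly on the risk-ratio scale (the mixture of cell
risks is linear in the baseline); odds-ratio inputs are mapped through the
logistic form per cell before mixing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PlanningScenario",
    "CoIntervention",
    "marginal_event_rate",
    "sample_size_binary",
    "sample_size_events",
    "analytic_power",
    "power_loss_curve",
    "planning_report",
]


@dataclass(frozen=True)
class CoIntervention:
    """An effective intervention in another randomisation.

    ``ratio`` is its effect vs control (risk ratio by default, or odds ratio
    with ``scale='or'``); ``fraction`` the share of patients allocated to it.
    """

    ratio: float
    fraction: float
    scale: str = "rr"

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("effect ratio must be positive")
        if not 0 <= self.fraction <= 1:
            raise ValueError("allocated fraction must lie in [0, 1]")


@dataclass
class PlanningScenario:
    """Inputs to power a single pairwise comparison.

    ``target_ratio`` is the effect (on ``target_scale``) the comparison is
    powered to detect; co_interventions describes effective interventions in
    other randomisations diluting the event rate.
    """

    p0: float
    target_ratio: float
    co_interventions: list[CoIntervention] = field(default_factory=list)
    target_scale: str = "rr"
    alpha: float = 0.025
    sided: int = 1
    power: float = 0.9
    n_comparisons: int = 1
    multiplicity: str = "none"  # none | bonferroni

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValueError("control event probability must be in (0, 1)")

    @property
    def adjusted_alpha(self) -> float:
        if self.multiplicity == "bonferroni" and self.n_comparisons > 1:
            return self.alpha / self.n_comparisons
        return self.alpha


def _cell_risk(p0: float, cos: tuple[CoIntervention, ...], received: tuple[int, ...]) -> float:
    """Event risk in one co-intervention allocation cell."""
    p = p0
    lor = 0.0
    for c, r in zip(cos, received):
        if not r:
            continue
        if c.scale == "rr":
            p *= c.ratio
        else:
            lor += math.log(c.ratio)
    if lor != 0.0:
        p = 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + lor))) if 0 < p < 1 else p
    return p


def marginal_event_rate(p0: float, co_interventions) -> float:
    """Diluted marginal control-group event rate under co-interventions.

    Expands the independent allocation cells (each co-intervention received
    or not) and mixes the per-cell risks by the allocation fractions:
    ``sum_cells prod(f or 1-f) * risk(cell)``.  With a single co-intervention
    of risk ratio r at fraction f this is ``(1-f)*p0 + f*r*p0``.
    """
    cos = tuple(
        c if isinstance(c, CoIntervention) else CoIntervention(**c) for c in co_interventions
    )
    total = 0.0
    for received in itertools.product((0, 1), repeat=len(cos)):
        w = 1.0
        for c, r in zip(cos, received):
            w *= c.fraction if r else (1.0 - c.fraction)
        total += w * _cell_risk(p0, cos, received)
    if not 0 < total < 1:
        raise ValueError(f"diluted event rate {total} outside (0, 1)")
    return total


def _apply_target(p1: float, ratio: float, scale: str) -> float:
    if scale == "rr":
        return p1 * ratio
    odds = p1 / (1 - p1) * ratio
    return odds / (1 + odds)


def sample_size_binary(scenario: PlanningScenario) -> int:
    """Patients per arm for a two-proportion comparison on the diluted rates.

    Normal approximation with pooled variance under the null:
    ``n = (z_a sqrt(2 p q) + z_b sqrt(p1 q1 + p2 q2))^2 / (p1 - p2)^2``.
    """
    p1 = marginal_event_rate(scenario.p0, scenario.co_interventions)
    p2 = _apply_target(p1, scenario.target_ratio, scenario.target_scale)
    if math.isclose(p1, p2):
        raise ValueError("null target effect: sample size is undefined (infinite)")
    alpha = scenario.adjusted_alpha
    za = stats.norm.ppf(1 - alpha / scenario.sided)
    zb = stats.norm.ppf(scenario.power)
    pbar = (p1 + p2) / 2
    n = (za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n /= (p1 - p2) ** 2
    return int(math.ceil(n))


def sample_size_events(scenario: PlanningScenario, accrual_rate: float | None = None) -> dict:
    """Events (Schoenfeld) for a time-to-event comparison; optional duration.

    ``target_ratio`` is read as a hazard ratio.  The same dilution applies to
    the pooled event rate, so the patient count needed to observe the events
    grows as co-interventions become effective; duration assumes constant
    accrual and the diluted event probability per patient.
    """
    alpha = scenario.adjusted_alpha
    za = stats.norm.ppf(1 - alpha / scenario.sided)
    zb = stats.norm.ppf(scenario.power)
    log_hr = math.log(scenario.target_ratio)
    if log_hr == 0:
        raise ValueError("null target effect: event count is undefined (infinite)")
    events = 4 * (za + zb) ** 2 / log_hr**2
    p_event = marginal_event_rate(scenario.p0, scenario.co_interventions)
    n_patients = math.ceil(events / p_event)
    out = {"events": int(math.ceil(events)), "patients_total": int(n_patients)}
    if accrual_rate:
        out["accrual_duration"] = n_patients / accrual_rate
    return out


def analytic_power(scenario: PlanningScenario, n_per_arm: int) -> float:
    """Normal-approximation power of the pooled-variance two-proportion test."""
    p1 = marginal_event_rate(scenario.p0, scenario.co_interventions)
    p2 = _apply_target(p1, scenario.target_ratio, scenario.target_scale)
    alpha = scenario.adjusted_alpha
    za = stats.norm.ppf(1 - alpha / scenario.sided)
    pbar = (p1 + p2) / 2
    se0 = math.sqrt(2 * pbar * (1 - pbar) / n_per_arm)
    se1 = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n_per_arm)
    return float(stats.norm.cdf((abs(p1 - p2) - za * se0) / se1))


def power_loss_curve(scenario: PlanningScenario, co_effect_grid, n_per_arm: int) -> np.ndarray:
    """Power at fixed n across a grid of co-intervention effect ratios.

    Each grid point replaces the ratio of every co-intervention in the
    scenario (allocation fractions unchanged); a ratio of 1 reproduces the
    base case.  For a binary outcome the curve is non-increasing as the
    co-intervention becomes more effective (smaller ratio).
    """
    grid = list(co_effect_grid)
    if not grid:
        raise ValueError("empty co-intervention effect grid")
    out = []
    for ratio in grid:
        cos = [
            CoIntervention(ratio, c.fraction, c.scale) for c in scenario.co_interventions
        ] or [CoIntervention(ratio, 0.5)]
        sc = PlanningScenario(
            scenario.p0, scenario.target_ratio, cos, scenario.target_scale,
            scenario.alpha, scenario.sided, scenario.power,
            scenario.n_comparisons, scenario.multiplicity,
        )
        out.append(analytic_power(sc, n_per_arm))
    return np.asarray(out)


def planning_report(scenario: PlanningScenario, co_effect_grid, json_path=None, csv_path=None) -> dict:
    """Scenario summary: diluted rate, n per arm, and the power grid at that n."""
    n = sample_size_binary(scenario)
    grid = list(co_effect_grid)
    powers = power_loss_curve(scenario, grid, n)
    report = {
        "scenario": {
            "p0": scenario.p0,
            "target_ratio": scenario.target_ratio,
            "target_scale": scenario.target_scale,
            "alpha": scenario.alpha,
            "sided": scenario.sided,
            "power": scenario.power,
            "multiplicity": scenario.multiplicity,
            "co_interventions": [
                {"ratio": c.ratio, "fraction": c.fraction, "scale": c.scale}
                for c in scenario.co_interventions
            ],
        },
        "diluted_control_rate": marginal_event_rate(scenario.p0, scenario.co_interventions),
        "n_per_arm": n,
        "power_grid": [
            {"co_effect_ratio": float(g), "power": float(p)} for g, p in zip(grid, powers)
        ],
    }
    if json_path is not None:
        import json

        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(report["power_grid"]).to_csv(csv_path, index=False)
    return report
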