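"""Synthetic patients and outcomes under a factorial effects model.

Patients arrive at a constant rate (or as a Poisson process), with
per-intervention eligibility and per-randomisation consent drawn
independently.  Outcomes are binary or exponential time-to-event.  Effects of
received research interventions combine multiplicatively — odds ratios on the
logit scale for binary outcomes (a risk-ratio option is available for
dilution arithmetic), hazard ratios for time-to-event — with optional
pairwise interaction multipliers (default 1: no interaction, the factorial
working assumption).

An intermediate outcome (an information-rich early endpoint used for interim
lack-of-benefit decisions) is generated from the same linear predictor scaled
by a concordance parameter ``rho``: at ``rho = 1`` treatment effects on the
intermediate equal those on the definitive outcome; at ``rho = 0`` the
intermediate is independent of treatment.

A secular-trend multiplier (per unit calendar time, off by default) lets the
baseline risk drift, which is what makes non-concurrent controls biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatientProfile",
    "OutcomeModel",
    "simulate_arrivals",
    "event_probability",
    "simulate_binary",
    "simulate_tte",
    "simulate_intermediate",
]


@dataclass
class PatientProfile:
    id: int
    arrival_time: float
    factors: dict = field(default_factory=dict)
    eligibility: dict = field(default_factory=dict)  # arm id -> bool (default True)
    consent: dict = field(default_factory=dict)  # randomisation id -> bool (default True)


@dataclass
class OutcomeModel:
    """Factorial effects model for the definitive and intermediate outcomes.

    ``baseline`` is the control-group event probability (binary) or hazard per
    unit time (time-to-event).  ``effects`` maps research intervention id to
    its effect ratio vs its control: odds ratio (``effect_scale='or'``) or
    risk ratio (``'rr'``) for binary outcomes, hazard ratio for time-to-event.
    ``interactions`` maps frozenset pairs of intervention ids to a multiplier
    applied on the same scale when both are received (default 1).
    ``secular_trend`` multiplies the baseline per unit calendar time
    (1.0 = no drift).  ``outcome_delay`` is the time from randomisation until
    a binary outcome becomes observable.
    """

    outcome_type: str = "binary"  # "binary" | "tte"
    baseline: float = 0.2
    effects: dict = field(default_factory=dict)
    effect_scale: str = "or"
    interactions: dict = field(default_factory=dict)
    intermediate_baseline: float | None = None
    intermediate_rho: float = 1.0
    follow_up: float = float("inf")
    secular_trend: float = 1.0
    outcome_delay: float = 0.0

    def __post_init__(self):
        if self.outcome_type not in ("binary", "tte"):
            raise ValueError(f"outcome_type must be binary/tte, got {self.outcome_type!r}")
        if self.outcome_type == "binary" and not 0 < self.baseline < 1:
            raise ValueError("baseline event probability must be in (0, 1)")
        if self.outcome_type == "tte" and self.baseline <= 0:
            raise ValueError("baseline hazard must be positive")
        if any(v <= 0 for v in self.effects.values()):
            raise ValueError("effect ratios must be positive")
        if not 0 <= self.intermediate_rho <= 1:
            raise ValueError("intermediate_rho must be in [0, 1]")
        if self.follow_up < 0:
            raise ValueError("follow_up must be non-negative")
        self.interactions = {frozenset(k): v for k, v in self.interactions.items()}

    def log_effect_sum(self, received) -> float:
        """Sum of log effect ratios + log interaction multipliers received."""
        recv = [a for a in received if a in self.effects]
        total = sum(math.log(self.effects[a]) for a in recv)
        for pair, mult in self.interactions.items():
            if pair <= set(received):
                total += math.log(mult)
        return total

    def baseline_at(self, time: float) -> float:
        if self.secular_trend == 1.0:
            return self.baseline
        return self.baseline * self.secular_trend**time


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_arrivals(
    rate: float,
    horizon: float,
    rng: np.random.Generator,
    eligibility_probs: dict | None = None,
    consent_probs: dict | None = None,
    factors: dict | None = None,
    poisson: bool = False,
) -> list[PatientProfile]:
    """Generate patient profiles arriving over ``[0, horizon]``.

    Default arrivals are deterministic at spacing ``1/rate``; with
    ``poisson=True`` the count is Poisson(rate*horizon) with uniform order
    statistics as arrival times.  ``eligibility_probs`` gives the probability
    each intervention is tolerated (independent per intervention);
    ``consent_probs`` the per-randomisation consent probability; ``factors``
    maps stratification factor name to its levels (sampled uniformly).
    """
    if rate <= 0:
        raise ValueError("arrival rate must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if poisson:
        n = int(rng.poisson(rate * horizon))
        times = np.sort(rng.uniform(0.0, horizon, size=n))
    else:
        n = int(math.floor(rate * horizon))
        times = np.arange(1, n + 1) / rate
    eligibility_probs = eligibility_probs or {}
    consent_probs = consent_probs or {}
    factors = factors or {}
    elig_draws = {a: rng.random(n) < p for a, p in eligibility_probs.items()}
    consent_draws = {r: rng.random(n) < p for r, p in consent_probs.items()}
    factor_draws = {f: rng.choice(levels, size=n) for f, levels in factors.items()}
    out = []
    for i in range(n):
        out.append(
            PatientProfile(
                id=i + 1,
                arrival_time=float(times[i]),
                factors={f: factor_draws[f][i] for f in factors},
                eligibility={a: bool(elig_draws[a][i]) for a in eligibility_probs},
                consent={r: bool(consent_draws[r][i]) for r in consent_probs},
            )
        )
    return out


def event_probability(received, model: OutcomeModel, time: float = 0.0) -> float:
    """Definitive event probability for one patient's received interventions."""
    if model.outcome_type != "binary":
        raise ValueError("event_probability applies to binary outcome models")
    p0 = model.baseline_at(time)
    lp = model.log_effect_sum(received)
    if model.effect_scale == "rr":
        return float(min(p0 * math.exp(lp), 1.0 - 1e-12))
    return float(_expit(_logit(p0) + lp))


def simulate_binary(received, model: OutcomeModel, rng: np.random.Generator, time: float = 0.0) -> int:
    """Draw the definitive binary event indicator for one patient."""
    return int(rng.random() < event_probability(received, model, time))


def simulate_tte(
    received,
    model: OutcomeModel,
    rng: np.random.Generator,
    time: float = 0.0,
) -> tuple[float, int]:
    """Draw (observed time, event indicator) under an exponential hazard.

    The hazard is ``baseline_at(arrival) * prod(HR) * interactions``;
    administrative censoring applies at ``model.follow_up``.
    """
    if model.outcome_type != "tte":
        raise ValueError("simulate_tte applies to time-to-event outcome models")
    hazard = model.baseline_at(time) * math.exp(model.log_effect_sum(received))
    t = float(rng.exponential(1.0 / hazard))
    if t <= model.follow_up:
        return t, 1
    return float(model.follow_up), 0


def intermediate_probability(received, model: OutcomeModel, time: float = 0.0) -> float:
    """Intermediate event probability: same linear predictor scaled by rho."""
    q0 = model.intermediate_baseline
    if q0 is None:
        raise ValueError("intermediate outcome is not configured (intermediate_baseline)")
    base = q0 * model.secular_trend**time if model.secular_trend != 1.0 else q0
    lp = model.intermediate_rho * model.log_effect_sum(received)
    if model.effect_scale == "rr":
        return float(min(base * math.exp(lp), 1.0 - 1e-12))
    return float(_expit(_logit(base) + lp))


def simulate_intermediate(received, model: OutcomeModel, rng: np.random.Generator, time: float = 0.0) -> int:
    """Draw the intermediate (early) binary outcome for one patient."""
    return int(rng.random() < intermediate_probability(received, model, time))
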