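"""Interim monitoring: look scheduling, stopping boundaries, decisions.

Look timing is driven either by calendar time or by the number of outcome
events pooled across *all* arms — never by per-comparison control-arm event
counts, because in a factorial design each comparison has a different control
group and revealing per-control event counts leaks information about
intervention effects.  ``control_event_audit`` computes those per-control
counts for Data Monitoring Committee reports only; the scheduler's interface
takes pooled event times and cannot see them.

Efficacy boundaries on the definitive outcome come in three families:
Haybittle-Peto (a fixed extreme interim threshold with a near-nominal final
test), O'Brien-Fleming (thresholds shrinking as information accrues,
``c * sqrt(K/k)`` with ``c`` solved so the total null crossing probability
equals alpha under equal information spacing), and boundaries derived from an
alpha-spending function (Lan-DeMets O'Brien-Fleming-like or Pocock-like),
computed by numerical integration of the group-sequential density recursion.

Lack-of-benefit (futility) rules are one-sided z thresholds per interim look
applied to the *intermediate* outcome, with z signed so that benefit is
positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MonitoringPlan",
    "LookResult",
    "next_look",
    "control_event_audit",
    "efficacy_boundary",
    "boundary_table",
    "gs_crossing_probabilities",
    "spending_boundaries",
    "evaluate_look",
]


@dataclass
class MonitoringPlan:
    """Interim analysis schedule and stopping rules.

    ``triggers`` lists the interim looks, each ``{"type": "events", "value": tau}``
    (tau-th pooled event across all arms) or ``{"type": "calendar", "time": t}``.
    The final analysis is look ``K = len(triggers) + 1``.  ``futility_bounds``
    gives the one-sided z threshold on the intermediate outcome at each
    interim look (None disables futility stopping).  ``alpha`` is the
    pairwise one-sided significance level.
    """

    triggers: list[dict] = field(default_factory=list)
    efficacy: str = "haybittle_peto"  # haybittle_peto | obrien_fleming | alpha_spending
    futility_bounds: list[float] | None = None
    alpha: float = 0.025
    haybittle_peto_p: float = 0.001  # two-sided interim p*
    spending: str = "obf"  # for alpha_spending: "obf" | "pocock"
    multiplicity: str = "none"  # none | bonferroni

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be a one-sided level in (0, 0.5)")
        values = [t.get("value", t.get("time")) for t in self.triggers]
        if any(v is None for v in values):
            raise ValueError("each trigger needs a 'value' (events) or 'time' (calendar)")
        if values != sorted(values) or len(set(values)) != len(values):
            raise ValueError("triggers must be strictly increasing")
        if self.futility_bounds is not None and len(self.futility_bounds) != len(self.triggers):
            raise ValueError("one futility bound per interim look required")

    @property
    def n_looks(self) -> int:
        return len(self.triggers) + 1

    def adjusted_alpha(self, n_comparisons: int) -> float:
        if self.multiplicity == "bonferroni" and n_comparisons > 1:
            return self.alpha / n_comparisons
        return self.alpha


@dataclass
class LookResult:
    look: int
    time: float
    pooled_events: int
    z_definitive: dict
    z_intermediate: dict
    boundary: float
    futility_bound: float | None
    decisions: dict  # research intervention id -> continue | stop_lack_of_benefit | stop_efficacy

    def to_report(self) -> dict:
        return {
            "look": self.look,
            "time": self.time,
            "pooled_events": self.pooled_events,
            "z_definitive": self.z_definitive,
            "z_intermediate": self.z_intermediate,
            "efficacy_boundary": self.boundary,
            "futility_bound": self.futility_bound,
            "decisions": self.decisions,
        }


def next_look(plan: MonitoringPlan, pooled_event_times=None, after: float = -math.inf):
    """Calendar time of the next interim look after ``after``, or None.

    Event triggers fire at the time of the tau-th event pooled across all
    arms; ``pooled_event_times`` is the sorted (or sortable) stream of event
    calendar times observed so far.  A trigger not yet reachable returns None
    (the caller falls back to the final analysis at data maturity).
    """
    times = np.sort(np.asarray(pooled_event_times if pooled_event_times is not None else []))
    candidates = []
    for trig in plan.triggers:
        if trig["type"] == "calendar":
            t = float(trig["time"])
        elif trig["type"] == "events":
            tau = int(trig["value"])
            if len(times) < tau:
                continue
            t = float(times[tau - 1])
        else:
            raise ValueError(f"unknown trigger type {trig['type']!r}")
        if t > after:
            candidates.append(t)
    return min(candidates) if candidates else None


def control_event_audit(arm_event_counts: dict, comparison: str) -> int:
    """Per-comparison control-arm event count, for DMC reports only.

    ``arm_event_counts`` maps combination labels (``"A0+B0"`` or tuples of
    arm ids) to event counts; the control arms of the comparison's
    randomisation are the combinations whose level in that randomisation is
    the control (e.g. for ``A1-vs-A0``, every combination containing A0).
    """
    try:
        _, control = comparison.split("-vs-")
    except ValueError as exc:
        raise ValueError(f"unknown comparison {comparison!r}") from exc
    total = 0
    seen = False
    for combo, count in arm_event_counts.items():
        levels = combo.split("+") if isinstance(combo, str) else list(combo)
        if control in levels:
            total += count
            seen = True
    if not seen and arm_event_counts:
        raise ValueError(f"comparison {comparison!r} matches no combination arm")
    return total


# ---------------------------------------------------------------------------
# Group-sequential numerics


def _simpson_weights(z: np.ndarray) -> np.ndarray:
    h = z[1] - z[0]
    w = np.ones(len(z))
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def gs_crossing_probabilities(bounds, info_fractions=None, sided: int = 2, grid_points: int = 801) -> np.ndarray:
    """Per-look first-crossing probabilities under the null.

    Uses the standard recursion for the sub-density of the sequentially
    computed z statistics ``Z_k`` (multivariate normal with
    ``cov(Z_j, Z_k) = sqrt(t_j / t_k)``) restricted to the continuation
    region, integrated by Simpson's rule on a grid spanning exactly the
    continuation region at each look.
    """
    bounds = np.asarray(bounds, dtype=float)
    K = len(bounds)
    t = np.asarray(info_fractions if info_fractions is not None else np.arange(1, K + 1) / K, dtype=float)
    if len(t) != K or np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("info fractions must be strictly increasing and positive")
    lo = -10.0  # effective -inf for one-sided continuation regions
    out = np.empty(K)
    z_prev: np.ndarray | None = None
    g_prev: np.ndarray | None = None
    mass_prev = 1.0
    for k in range(K):
        lower = -bounds[k] if sided == 2 else lo
        z = np.linspace(lower, bounds[k], grid_points)
        if k == 0:
            g = stats.norm.pdf(z)
            inside = (
                stats.norm.cdf(bounds[0]) - stats.norm.cdf(lower)
                if sided == 2
                else stats.norm.cdf(bounds[0])
            )
        else:
            ratio = math.sqrt(t[k - 1] / t[k])
            s = math.sqrt(1.0 - t[k - 1] / t[k])
            w_prev = _simpson_weights(z_prev)
            # transition density: rows = previous z, cols = new z
            trans = stats.norm.pdf((z[None, :] - ratio * z_prev[:, None]) / s) / s
            g = (w_prev * g_prev) @ trans
            inside = float(np.sum(_simpson_weights(z) * g))
        out[k] = mass_prev - inside
        mass_prev = inside
        z_prev, g_prev = z, g
    return out


def _obf_constant(K: int, alpha: float, sided: int) -> float:
    def total(c):
        bounds = c * np.sqrt(K / np.arange(1, K + 1))
        return gs_crossing_probabilities(bounds, sided=sided).sum() - alpha

    return optimize.brentq(total, 0.5, 8.0, xtol=1e-8)


def _spending_function(name: str, alpha: float):
    if name == "obf":
        za = stats.norm.ppf(1 - alpha / 2)
        return lambda t: 2.0 * (1.0 - stats.norm.cdf(za / math.sqrt(t))) if t > 0 else 0.0
    if name == "pocock":
        return lambda t: alpha * math.log(1.0 + (math.e - 1.0) * t)
    raise ValueError(f"unknown spending function {name!r}")


def spending_boundaries(K: int, alpha: float, spending="obf", info_fractions=None, sided: int = 2) -> np.ndarray:
    """Boundaries from an alpha-spending function by sequential solving."""
    t = np.asarray(info_fractions if info_fractions is not None else np.arange(1, K + 1) / K, dtype=float)
    f = _spending_function(spending, alpha) if isinstance(spending, str) else spending
    bounds: list[float] = []
    for k in range(K):
        spent = f(t[k]) if k < K - 1 else alpha  # spend everything at the final look
        def cum(b):
            probs = gs_crossing_probabilities(np.array(bounds + [b]), t[: k + 1], sided=sided)
            return probs.sum() - spent
        bounds.append(optimize.brentq(cum, 0.1, 8.0, xtol=1e-8))
    return np.asarray(bounds)


def efficacy_boundary(
    kind: str,
    k: int,
    K: int,
    alpha: float,
    sided: int = 2,
    p_star: float = 0.001,
    spending: str = "obf",
    info_fractions=None,
) -> float:
    """Critical z value for the definitive outcome at look ``k`` of ``K``.

    ``alpha`` and ``p_star`` are interpreted on the ``sided`` scale requested
    (``sided=2`` gives the conventional symmetric boundaries).
    """
    if not 1 <= k <= K:
        raise ValueError(f"look index k={k} outside 1..K={K}")
    if not 0 < alpha < 0.5 if sided == 1 else not 0 < alpha < 1:
        raise ValueError("alpha out of range")
    tail = alpha / sided
    if K == 1:
        return float(stats.norm.ppf(1 - tail))
    if kind == "haybittle_peto":
        if k < K:
            return float(stats.norm.ppf(1 - p_star / sided))
        return float(stats.norm.ppf(1 - tail))
    if kind == "obrien_fleming":
        if info_fractions is not None:
            warnings.warn("obrien_fleming assumes equal spacing; use alpha_spending for unequal looks")
        c = _obf_constant(K, alpha, sided)
        return float(c * math.sqrt(K / k))
    if kind == "alpha_spending":
        return float(spending_boundaries(K, alpha, spending, info_fractions, sided)[k - 1])
    raise ValueError(f"unknown boundary kind {kind!r}")


def boundary_table(kind: str, K: int, alpha: float, **kwargs) -> np.ndarray:
    """All K boundaries for a family (exportable as a CSV column)."""
    return np.array([efficacy_boundary(kind, k, K, alpha, **kwargs) for k in range(1, K + 1)])


def evaluate_look(
    plan: MonitoringPlan,
    look: int,
    analyses: dict,
    open_comparisons: list[str],
    time: float = 0.0,
    pooled_events: int = 0,
    n_comparisons: int | None = None,
) -> LookResult:
    """Apply the stopping rules at one look.

    ``analyses`` maps comparison id to ``{"z_definitive": ..., "z_intermediate": ...}``
    computed by the analysis engine on concurrent data only (z signed so
    benefit is positive).  Efficacy stops use the definitive outcome against
    the look's boundary; lack-of-benefit stops use the intermediate outcome
    against the futility bound (interim looks only).
    """
    K = plan.n_looks
    alpha = plan.adjusted_alpha(n_comparisons or len(open_comparisons) or 1)
    bound = efficacy_boundary(
        plan.efficacy, look, K, alpha, sided=1, p_star=plan.haybittle_peto_p, spending=plan.spending
    )
    fut = None
    if plan.futility_bounds is not None and look <= len(plan.futility_bounds):
        fut = plan.futility_bounds[look - 1]
    decisions, z_def, z_int = {}, {}, {}
    for cid in open_comparisons:
        if cid not in analyses:
            raise ValueError(f"missing analysis for open comparison {cid!r}")
        a = analyses[cid]
        zd = a.get("z_definitive")
        zi = a.get("z_intermediate")
        z_def[cid], z_int[cid] = zd, zi
        arm = cid.split("-vs-")[0]
        if zd is not None and zd > bound:
            decisions[arm] = "stop_efficacy"
        elif fut is not None and look < K and zi is not None and zi < fut:
            decisions[arm] = "stop_lack_of_benefit"
        else:
            decisions[arm] = "continue"
    return LookResult(look, time, pooled_events, z_def, z_int, bound, fut, decisions)
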