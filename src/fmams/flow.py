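"""Deterministic patient-flow accounting for factorial-MAMS designs.

Given a design trajectory and per-comparison patient targets, the planner
computes, stage by stage, how many patients are randomised and how many
contribute to each pairwise comparison.  A patient randomised in randomisation
X contributes to the comparison ``Xi vs X0`` with expected fraction
``(w_i + w_0) / sum(w)`` over X's active arms (equal weights in a k-way
randomisation: ``2/k``).  Accrual is tracked on this allocation-expectation
scale throughout the package, so trial milestones — scheme changes at
comparison completion and the end of recruitment — are deterministic given
the adaptation schedule.

Stages advance at every scheduled adaptation and at every comparison
completion: completing the last comparison of a randomisation retires the
randomisation; completing one comparison of a >=3-way randomisation retires
that research arm only.  Recruitment ends when every comparison is complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .design import (
    Adaptation,
    DesignError,
    TrialDesign,
    apply_adaptation,
    comparison_id,
)

__all__ = ["StagePlan", "FlowTable", "FlowTracker", "plan_flow", "reporting_milestones", "timeline_export"]


@dataclass
class ComparisonState:
    cid: str
    randomisation_id: str
    research_arm: str
    control_arm: str
    target: int
    cum: Fraction = Fraction(0)
    status: str = "open"  # open | completed | stopped | pending

    @property
    def remaining(self) -> Fraction:
        return Fraction(self.target) - self.cum


@dataclass
class StagePlan:
    stage_index: int
    label: str
    n_randomised: int
    contributions: dict[str, Fraction]


@dataclass
class FlowTable:
    rows: list[StagePlan]
    totals: dict[str, Fraction]
    total_randomised: int
    milestones: dict[str, int]
    unreachable: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        comps = list(self.totals)
        recs = []
        for row in self.rows:
            rec = {"stage": row.stage_index, "design": row.label, "randomised": row.n_randomised}
            for c in comps:
                v = row.contributions.get(c)
                rec[c] = float(v) if v is not None else None
            recs.append(rec)
        rec = {"stage": "total", "design": "", "randomised": self.total_randomised}
        rec.update({c: float(self.totals[c]) for c in comps})
        recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ceil_multiple(x: Fraction, step: int) -> int:
    """Smallest positive integer multiple of ``step`` that is >= x."""
    n = math.ceil(x / step)
    return max(int(n), 1) * step


class FlowTracker:
    """Online accrual accounting shared by the planner and the simulator.

    Holds the evolving design, per-comparison expected contributions (exact
    rational arithmetic), and the queue of scheduled adaptations.
    """

    def __init__(self, design: TrialDesign):
        self.design = design
        self.cum_n = 0
        self.comparisons: dict[str, ComparisonState] = {}
        self.pending = sorted(design.planned_adaptations, key=lambda a: a.time)
        self.unreachable: list[str] = []
        self.applied: list[Adaptation] = []  # adaptations applied, in order
        self._rates_cache: dict[str, Fraction] | None = None
        self._sync_comparisons()

    # -- state ----------------------------------------------------------
    def _sync_comparisons(self) -> None:
        stage = self.design.current_stage
        for r in stage.open_randomisations():
            ctrl = r.control.id
            for arm in r.research_arms:
                cid = comparison_id(arm.id, ctrl)
                if cid not in self.comparisons:
                    self.comparisons[cid] = ComparisonState(
                        cid, r.id, arm.id, ctrl, self.design.target_for(cid)
                    )

    def rates(self) -> dict[str, Fraction]:
        """Expected contribution per randomised patient, per open comparison."""
        if self._rates_cache is not None:
            return self._rates_cache
        stage = self.design.current_stage
        out: dict[str, Fraction] = {}
        for r in stage.open_randomisations():
            total_w = sum((a.weight for a in r.arms), Fraction(0))
            elig = Fraction(self.design.eligibility_fractions.get(r.id, 1))
            for arm in r.research_arms:
                cid = comparison_id(arm.id, r.control.id)
                c = self.comparisons.get(cid)
                if c is not None and c.status == "open":
                    out[cid] = elig * (arm.weight + r.control.weight) / total_w
        self._rates_cache = out
        return out

    def open_unfinished(self) -> list[ComparisonState]:
        return [c for c in self.comparisons.values() if c.status == "open"]

    def done(self) -> bool:
        return not self.open_unfinished() and not self.pending

    # -- planning -------------------------------------------------------
    def next_segment(self) -> int:
        """Patients until the next deterministic event (adaptation/completion)."""
        rates = self.rates()
        denoms = [r.denominator for r in rates.values()] or [1]
        step = math.lcm(*denoms)
        candidates: list[int] = []
        for cid, rate in rates.items():
            c = self.comparisons[cid]
            if rate > 0 and c.remaining > 0:
                candidates.append(_ceil_multiple(c.remaining / rate, step))
        if self.pending:
            candidates.append(int(self.pending[0].time) - self.cum_n)
        live = [d for d in candidates if d > 0]
        if not live:
            stuck = [c.cid for c in self.open_unfinished() if self.rates().get(c.cid, 0) == 0]
            self.unreachable.extend(s for s in stuck if s not in self.unreachable)
            for s in stuck:
                self.comparisons[s].status = "stopped"
            if stuck:
                self._rates_cache = None
            return 0
        return min(live)

    def advance(self, n: int) -> dict[str, Fraction]:
        """Recruit ``n`` patients at current rates; returns contributions added."""
        rates = self.rates()
        added = {cid: rate * n for cid, rate in rates.items()}
        for cid, inc in added.items():
            self.comparisons[cid].cum += inc
        self.cum_n += n
        return added

    def due_events(self) -> list[tuple[str, object]]:
        events: list[tuple[str, object]] = []
        while self.pending and self.pending[0].time <= self.cum_n:
            events.append(("adaptation", self.pending.pop(0)))
        for c in self.open_unfinished():
            if c.cum >= c.target:
                events.append(("completion", c.cid))
        return events

    def apply_events(self, events) -> bool:
        """Apply due events; returns True if the scheme changed (new stage)."""
        changed = False
        completions = [payload for kind, payload in events if kind == "completion"]
        for cid in completions:
            self.comparisons[cid].status = "completed"
        if completions:
            self._rates_cache = None
        for kind, payload in events:
            if kind == "adaptation":
                self.apply_adaptation(payload)
                changed = True
        for cid in completions:
            c = self.comparisons[cid]
            # retiring the completed arm (or whole randomisation) opens a new
            # stage; skipped when the trial is over and no stage follows
            if self.open_unfinished() or self.pending:
                rand = self.design.current_stage.randomisation(c.randomisation_id)
                if rand.status == "open" and any(a.id == c.research_arm for a in rand.arms):
                    self.apply_adaptation(
                        Adaptation("drop_completed", c.research_arm, time=self.cum_n)
                    )
                    changed = True
        return changed

    def apply_adaptation(self, ad: Adaptation) -> None:
        self.design = apply_adaptation(self.design, ad, time=self.cum_n)
        # a stop ends the stopped arm's comparisons
        if ad.kind in ("stop_lack_of_benefit", "stop_efficacy"):
            for c in self.comparisons.values():
                if c.research_arm == ad.target and c.status == "open":
                    c.status = "stopped"
        self._sync_comparisons()
        self._rates_cache = None
        self.applied.append(ad)

    def stop_arm(self, arm_id: str, kind: str) -> None:
        """Decision-driven stop (from interim monitoring)."""
        self.apply_adaptation(Adaptation(kind, arm_id, time=self.cum_n))


def plan_flow(design: TrialDesign) -> FlowTable:
    """Deterministic stage-by-stage patient-flow table for a design.

    Adaptation times must be expressed as cumulative patients randomised.
    Raises nothing on an unreachable target: the comparison is flagged in
    ``FlowTable.unreachable`` instead.
    """
    tracker = FlowTracker(design)
    rows: list[StagePlan] = []
    guard = 0
    while not tracker.done():
        guard += 1
        if guard > 10_000:
            raise DesignError("flow planning did not terminate; check targets/adaptations")
        events = tracker.due_events()
        if events:
            tracker.apply_events(events)
            continue
        delta = tracker.next_segment()
        if delta == 0:
            break
        stage = tracker.design.current_stage
        contributions = tracker.advance(delta)
        rows.append(StagePlan(stage.index, stage.label(), delta, contributions))

    comps = list(tracker.comparisons)
    totals = {
        cid: sum((row.contributions.get(cid, Fraction(0)) for row in rows), Fraction(0))
        for cid in comps
    }
    table = FlowTable(
        rows=rows,
        totals=totals,
        total_randomised=sum(r.n_randomised for r in rows),
        milestones=_milestones(rows, tracker),
        unreachable=tracker.unreachable,
    )
    return table


def _milestones(rows: list[StagePlan], tracker: FlowTracker) -> dict[str, int]:
    out: dict[str, int] = {}
    for cid, c in tracker.comparisons.items():
        if c.status != "completed":
            continue
        cum_c = Fraction(0)
        cum_n = 0
        for row in rows:
            cum_c += row.contributions.get(cid, Fraction(0))
            cum_n += row.n_randomised
            if cum_c >= c.target:
                out[cid] = cum_n
                break
    return out


def reporting_milestones(flow: FlowTable) -> dict[str, int]:
    """Cumulative patients randomised when each comparison can be reported.

    Incomplete comparisons are absent from the map (they are listed in
    ``flow.unreachable``).
    """
    return dict(flow.milestones)


def timeline_export(flow: FlowTable, accrual_rate: float, path=None) -> pd.DataFrame:
    """Gantt-style calendar segments per comparison (start/end of recruitment).

    Segment lengths are stage patient counts divided by the accrual rate.
    """
    if accrual_rate <= 0:
        raise DesignError("accrual_rate must be positive")
    recs = []
    for cid in flow.totals:
        cum_n = 0
        start = None
        end = None
        cum_c = Fraction(0)
        for row in flow.rows:
            contrib = row.contributions.get(cid, Fraction(0))
            if contrib > 0 and start is None:
                start = cum_n
            cum_n += row.n_randomised
            cum_c += contrib
            if contrib > 0:
                end = cum_n
        if start is None:
            continue
        if cid in flow.milestones:
            end = flow.milestones[cid]
        recs.append(
            {
                "comparison": cid,
                "start": start / accrual_rate,
                "end": end / accrual_rate,
                "patients": float(cum_c),
            }
        )
    df = pd.DataFrame.from_records(recs, columns=["comparison", "start", "end", "patients"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
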