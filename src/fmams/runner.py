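"""Single-trial simulation and Monte-Carlo operating characteristics.

``run_trial`` composes the whole pipeline: synthetic arrivals, sequential
stratified block randomisation under the evolving scheme, outcome generation
under the factorial effects model, interim monitoring with stopping
decisions, and final concurrent-control analyses.  Per-comparison information
accrual is tracked on the allocation-expectation scale (the same accounting
the deterministic planner uses), so with stopping disabled the realised stage
boundaries reproduce ``plan_flow`` exactly for any seed.

Randomness is split into named substreams (arrivals, randomisation, outcomes)
derived from one seed, so adding draws to one component never perturbs the
others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .analysis import ComparisonResult, select_concurrent, stage_stratified_test
from .dataset import TrialData
from .design import TrialDesign
from .flow import FlowTracker, plan_flow
from .monitoring import MonitoringPlan, efficacy_boundary, evaluate_look, next_look
from .outcomes import (
    OutcomeModel,
    simulate_binary,
    simulate_intermediate,
    simulate_tte,
)
from .randomisation import Randomiser

__all__ = ["TrialResult", "OperatingCharacteristics", "run_trial", "run_monte_carlo"]


@dataclass
class ComparisonOutcome:
    comparison: str
    result: ComparisonResult | None
    decision: str  # completed | stop_lack_of_benefit | stop_efficacy | unreachable
    rejected: bool
    stopped_at_look: int | None = None
    contribution_n: int = 0


@dataclass
class TrialResult:
    seed: int
    stage_counts: dict[int, int]  # realised patients randomised per stage
    comparisons: dict[str, ComparisonOutcome]
    total_n: int
    total_events: int
    duration: float
    look_reports: list[dict]
    data: TrialData
    randomiser: Randomiser
    design: TrialDesign

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "total_n": self.total_n,
            "total_events": self.total_events,
            "duration": self.duration,
            "stage_counts": self.stage_counts,
            "comparisons": {
                cid: {
                    "decision": c.decision,
                    "rejected": c.rejected,
                    "estimate": None if c.result is None else c.result.estimate,
                    "z": None if c.result is None else c.result.z,
                    "n": c.contribution_n,
                }
                for cid, c in self.comparisons.items()
            },
        }


@dataclass
class OperatingCharacteristics:
    reps: int
    per_comparison: dict[str, dict]
    familywise_error: float | None
    fwer_se: float | None
    expected_total_n: float
    expected_duration: float
    null_comparisons: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame.from_dict(self.per_comparison, orient="index")

    def to_json(self, path=None):
        payload = {
            "reps": self.reps,
            "per_comparison": self.per_comparison,
            "familywise_error": self.familywise_error,
            "fwer_se": self.fwer_se,
            "expected_total_n": self.expected_total_n,
            "expected_duration": self.expected_duration,
            "null_comparisons": self.null_comparisons,
        }
        text = json.dumps(payload, indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return path


class _PatientStore:
    """Accumulates per-patient rows and materialises TrialData views."""

    def __init__(self, rand_ids_hint):
        self.pid: list[int] = []
        self.arrival: list[float] = []
        self.stage: list[int] = []
        self.assignment: dict[str, list] = {}
        self.mechanism: dict[str, list] = {}
        self.subset: dict[str, list] = {}
        self.event: list[int] = []
        self.tte: list[float] = []
        self.outcome_time: list[float] = []
        self.intermediate: list[int] = []

    def add(self, pid, arrival, stage, records, event, tte, out_time, inter):
        i = len(self.pid)
        self.pid.append(pid)
        self.arrival.append(arrival)
        self.stage.append(stage)
        seen = set()
        for rec in records:
            rid = rec.randomisation_id
            seen.add(rid)
            for store, val in (
                (self.assignment, rec.assignment),
                (self.mechanism, rec.mechanism),
                (self.subset, rec.eligible_subset),
            ):
                col = store.setdefault(rid, [None] * i + [])
                while len(col) < i:
                    col.append(None)
                col.append(val)
        for rid in set(self.assignment) - seen:  # randomisation not yet open
            for store in (self.assignment, self.mechanism, self.subset):
                store[rid].append(None)
        self.event.append(event)
        self.tte.append(tte)
        self.outcome_time.append(out_time)
        self.intermediate.append(inter)

    def to_data(self, design, outcome_type, upto_time=None) -> TrialData:
        n = len(self.pid)
        mask = np.ones(n, dtype=bool)
        observed = np.asarray(self.outcome_time[:n])
        if upto_time is not None:
            mask = observed <= upto_time
        rand_ids = list(self.assignment)

        def col(values, dtype=None):
            arr = np.asarray(values[:n], dtype=dtype) if dtype else np.asarray(values[:n], dtype=object)
            return arr[mask]

        pad = lambda lst: lst[:n] + [None] * (n - len(lst[:n]))
        return TrialData(
            design=design,
            randomisation_ids=rand_ids,
            patient_id=np.asarray(self.pid[:n])[mask],
            arrival=np.asarray(self.arrival[:n])[mask],
            stage=np.asarray(self.stage[:n])[mask],
            assignment={r: col(pad(self.assignment[r])) for r in rand_ids},
            mechanism={r: col(pad(self.mechanism[r])) for r in rand_ids},
            eligible_subset={r: [s for s, m in zip(pad(self.subset[r]), mask) if m] for r in rand_ids},
            outcome_type=outcome_type,
            event=np.asarray(self.event[:n], dtype=np.int8)[mask],
            time_to_event=np.asarray(self.tte[:n])[mask],
            outcome_time=observed[mask],
            intermediate=np.asarray(self.intermediate[:n], dtype=np.int8)[mask],
        )


def run_trial(
    design: TrialDesign,
    model: OutcomeModel,
    plan: MonitoringPlan | None = None,
    seed: int = 0,
    stopping_enabled: bool = True,
    block_multiples: tuple[int, ...] = (1, 2),
    eligibility_probs: dict | None = None,
    consent_probs: dict | None = None,
    poisson_arrivals: bool = False,
    adopt_winner: bool = True,
    max_patients: int | None = None,
) -> TrialResult:
    """Simulate one complete factorial-MAMS trial.

    Deterministic given ``seed``.  Scheduled adaptations fire at their
    cumulative-patient times; comparisons complete when their expected
    contribution reaches target; interim looks follow ``plan`` and, when
    ``stopping_enabled``, their decisions stop arms via the adaptation
    operators.  Returns realised flow, per-comparison analyses and decisions,
    look reports and the full patient-level dataset.
    """
    ss = np.random.SeedSequence(seed)
    arr_rng, rand_rng, out_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    tracker = FlowTracker(design)
    randomiser = Randomiser(tracker.design, rand_rng, block_multiples)
    store = _PatientStore(None)
    stage_counts: dict[int, int] = {}
    look_reports: list[dict] = []
    decisions: dict[str, tuple[str, int]] = {}  # research arm -> (decision, look)
    event_times: list[float] = []
    n_interims_done = 0
    last_look_time = -math.inf
    spacing = 1.0 / design.accrual_rate
    next_arrival = 0.0
    eligibility_probs = eligibility_probs or {}
    consent_probs = consent_probs or {}
    factor_levels = design.stratification_factors or {}
    total_comparisons = len(design.comparison_ids())
    pid = 0

    def drain_adaptations(offset: int) -> None:
        for ad in tracker.applied[offset:]:
            randomiser.bind(tracker.design)
            randomiser.adapt(ad)

    def do_look(look_time: float, look_index: int) -> None:
        nonlocal last_look_time
        open_cids = [c.cid for c in tracker.open_unfinished()]
        if not open_cids:
            return
        data = store.to_data(tracker.design, model.outcome_type, upto_time=look_time)
        analyses = {}
        for cid in open_cids:
            aset = select_concurrent(data, cid)
            res = stage_stratified_test(data, aset)
            z_int = None
            if model.intermediate_baseline is not None:
                z_int = _intermediate_z(data, aset)
            analyses[cid] = {
                "z_definitive": None if res.no_information else res.z,
                "z_intermediate": z_int,
            }
        result = evaluate_look(
            plan, look_index, analyses, open_cids,
            time=look_time, pooled_events=int(np.sum([t <= look_time for t in event_times])),
            n_comparisons=total_comparisons,
        )
        look_reports.append(result.to_report())
        last_look_time = look_time
        if not stopping_enabled:
            return
        offset = len(tracker.applied)
        for arm, decision in result.decisions.items():
            if decision == "continue":
                continue
            decisions[arm] = (decision, look_index)
            tracker.stop_arm(arm, decision)
            if decision == "stop_efficacy" and not adopt_winner:
                # winner not adopted: discontinued 2-way reverts to control
                rand = next(
                    r for r in tracker.design.current_stage.scheme
                    if r.fixed_delivery == arm
                ) if any(r.fixed_delivery == arm for r in tracker.design.current_stage.scheme) else None
                if rand is not None:
                    rand.fixed_delivery = rand.control.id if design.deliver_control_after_stop else None
        drain_adaptations(offset)

    while True:
        # deterministic events due before the next patient
        offset = len(tracker.applied)
        events = tracker.due_events()
        if events:
            tracker.apply_events(events)
            drain_adaptations(offset)
            continue
        if tracker.done() or not tracker.open_unfinished():
            break
        if max_patients is not None and tracker.cum_n >= max_patients:
            break
        # interim looks falling before the next arrival
        arrival = next_arrival + (arr_rng.exponential(spacing) if poisson_arrivals else spacing)
        if plan is not None and n_interims_done < len(plan.triggers):
            look_time = next_look(plan, event_times, after=last_look_time)
            while look_time is not None and look_time <= arrival and n_interims_done < len(plan.triggers):
                n_interims_done += 1
                do_look(look_time, n_interims_done)
                look_time = next_look(plan, event_times, after=last_look_time)
            if tracker.done() or not tracker.open_unfinished():
                continue
        next_arrival = arrival
        pid += 1
        profile = _draw_profile(pid, arrival, arr_rng, eligibility_probs, consent_probs, factor_levels)
        stage = tracker.design.current_stage
        records = randomiser.randomise_patient(profile, stage_index=stage.index, time=arrival)
        received = [r.assignment for r in records if r.assignment is not None]
        if model.outcome_type == "binary":
            ev = simulate_binary(received, model, out_rng, time=arrival)
            tte_val = math.nan
            out_time = arrival + model.outcome_delay
            if ev:
                event_times.append(out_time)
        else:
            tte_val, ev = simulate_tte(received, model, out_rng, time=arrival)
            out_time = arrival + tte_val
            if ev:
                event_times.append(out_time)
        inter = (
            simulate_intermediate(received, model, out_rng, time=arrival)
            if model.intermediate_baseline is not None
            else 0
        )
        store.add(pid, arrival, stage.index, records, ev, tte_val, out_time, inter)
        stage_counts[stage.index] = stage_counts.get(stage.index, 0) + 1
        tracker.advance(1)

    # data maturity: all outcomes observed; final analysis per comparison
    duration = next_arrival + (model.follow_up if model.outcome_type == "tte" else model.outcome_delay)
    data = store.to_data(tracker.design, model.outcome_type)
    alpha = plan.adjusted_alpha(total_comparisons) if plan is not None else 0.025
    K = plan.n_looks if plan is not None else 1
    final_bound = (
        efficacy_boundary(plan.efficacy, K, K, alpha, sided=1,
                          p_star=plan.haybittle_peto_p, spending=plan.spending)
        if plan is not None
        else float(sps.norm.ppf(1 - alpha))
    )
    comparisons: dict[str, ComparisonOutcome] = {}
    for cid, comp in tracker.comparisons.items():
        aset = select_concurrent(data, cid)
        res = stage_stratified_test(data, aset) if aset.n else None
        arm = comp.research_arm
        if arm in decisions:
            decision, look = decisions[arm]
            rejected = decision == "stop_efficacy"
        else:
            decision = "completed" if comp.status == "completed" else comp.status
            look = None
            rejected = bool(res is not None and not res.no_information and res.z > final_bound)
        comparisons[cid] = ComparisonOutcome(
            cid, res, decision, rejected, look, contribution_n=aset.n
        )
    return TrialResult(
        seed=seed,
        stage_counts=stage_counts,
        comparisons=comparisons,
        total_n=tracker.cum_n,
        total_events=int(np.sum(data.event)),
        duration=duration,
        look_reports=look_reports,
        data=data,
        randomiser=randomiser,
        design=tracker.design,
    )


def _draw_profile(pid, arrival, rng, eligibility_probs, consent_probs, factor_levels):
    from .outcomes import PatientProfile

    return PatientProfile(
        id=pid,
        arrival_time=arrival,
        factors={f: levels[int(rng.integers(len(levels)))] for f, levels in factor_levels.items()},
        eligibility={a: bool(rng.random() < p) for a, p in eligibility_probs.items()},
        consent={r: bool(rng.random() < p) for r, p in consent_probs.items()},
    )


def _intermediate_z(data: TrialData, aset) -> float | None:
    """Stage-stratified CMH z on the intermediate outcome (benefit-positive)."""
    from .analysis import _mantel_haenszel, _mh_tables, _informative

    idx = aset.indices
    treat = data.assignment[aset.randomisation_id][idx] == aset.research_arm
    tables = [t for t in _mh_tables(treat, data.intermediate[idx].astype(bool), data.stage[idx].astype(int)) if _informative(t)]
    if not tables:
        return None
    _, _, z = _mantel_haenszel(tables)
    return None if math.isnan(z) else z


def run_monte_carlo(
    design: TrialDesign,
    model: OutcomeModel,
    plan: MonitoringPlan | None = None,
    reps: int = 100,
    base_seed: int = 0,
    **trial_kwargs,
) -> OperatingCharacteristics:
    """Replicate ``run_trial`` with seeds ``base_seed + i`` and aggregate.

    Reports per-comparison rejection probability (type-I error under a null
    effect, power otherwise), stop probabilities and mean analysed n, plus
    the familywise error over the comparisons whose true effect is null and
    expected trial size/duration, all with Monte-Carlo standard errors.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cids = design.comparison_ids()
    null_cids = [
        cid for cid in cids if model.effects.get(cid.split("-vs-")[0], 1.0) == 1.0
    ]
    tallies = {cid: {"reject": 0, "lob": 0, "eff": 0, "n": 0.0} for cid in cids}
    any_null_reject = 0
    tot_n = 0.0
    tot_dur = 0.0
    for i in range(reps):
        tr = run_trial(design, model, plan, seed=base_seed + i, **trial_kwargs)
        null_rejected = False
        for cid in cids:
            c = tr.comparisons.get(cid)
            if c is None:
                continue
            t = tallies[cid]
            t["reject"] += c.rejected
            t["lob"] += c.decision == "stop_lack_of_benefit"
            t["eff"] += c.decision == "stop_efficacy"
            t["n"] += c.contribution_n
            if c.rejected and cid in null_cids:
                null_rejected = True
        any_null_reject += null_rejected
        tot_n += tr.total_n
        tot_dur += tr.duration

    def rate(x):
        p = x / reps
        return p, math.sqrt(p * (1 - p) / reps)

    per_comparison = {}
    for cid, t in tallies.items():
        p_rej, se_rej = rate(t["reject"])
        p_lob, _ = rate(t["lob"])
        p_eff, _ = rate(t["eff"])
        per_comparison[cid] = {
            "rejection_probability": p_rej,
            "rejection_se": se_rej,
            "p_stop_lack_of_benefit": p_lob,
            "p_stop_efficacy": p_eff,
            "mean_analysed_n": t["n"] / reps,
            "null": cid in null_cids,
        }
    fwer, fwer_se = rate(any_null_reject) if null_cids else (None, None)
    return OperatingCharacteristics(
        reps=reps,
        per_comparison=per_comparison,
        familywise_error=fwer,
        fwer_se=fwer_se,
        expected_total_n=tot_n / reps,
        expected_duration=tot_dur / reps,
        null_comparisons=null_cids,
    )
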