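"""Factorial-MAMS trial designs and their adaptation operators.

A factorial-MAMS design is a set of concurrent randomisations (each a
research-vs-control comparison set) evolving over time.  Every change of the
randomisation scheme — stopping an arm, adding an arm or a whole
randomisation, or retiring a completed comparison — opens a new *stage*.
Stages are the unit of concurrency for the analysis: a patient's concurrent
controls are the control patients randomised during stages in which the
comparator research arm was open.
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Arm",
    "Randomisation",
    "Stage",
    "Adaptation",
    "TrialDesign",
    "DesignError",
    "make_factorial_design",
    "enumerate_arms",
    "apply_adaptation",
    "load_design",
    "dump_design",
]

CONTROL = "control"
RESEARCH = "research"

ADAPTATION_KINDS = (
    "stop_lack_of_benefit",
    "stop_efficacy",
    "add_randomisation",
    "add_intervention",
    "drop_completed",
)


class DesignError(ValueError):
    """Raised when a design or adaptation violates its invariants."""


@dataclass(frozen=True)
class Arm:
    """One intervention within a randomisation (e.g. ``A1``)."""

    id: str
    role: str  # "control" or "research"
    weight: Fraction = Fraction(1)

    def __post_init__(self):
        if self.role not in (CONTROL, RESEARCH):
            raise DesignError(f"arm {self.id!r}: role must be control/research, got {self.role!r}")
        object.__setattr__(self, "weight", Fraction(self.weight))
        if self.weight <= 0:
            raise DesignError(f"arm {self.id!r}: allocation weight must be positive")


@dataclass
class Randomisation:
    """A single randomisation (e.g. 'randomisation A': A1 vs A0)."""

    id: str
    position: int
    arms: list[Arm]
    status: str = "open"  # "open" | "discontinued"
    # arm delivered to everyone once discontinued (control by default, or the
    # efficacy winner when adopt_winner applies); None => nothing delivered
    fixed_delivery: str | None = None

    @property
    def control(self) -> Arm:
        ctrls = [a for a in self.arms if a.role == CONTROL]
        if len(ctrls) != 1:
            raise DesignError(f"randomisation {self.id!r}: exactly one control required")
        return ctrls[0]

    @property
    def research_arms(self) -> list[Arm]:
        return [a for a in self.arms if a.role == RESEARCH]

    def arm(self, arm_id: str) -> Arm:
        for a in self.arms:
            if a.id == arm_id:
                return a
        raise DesignError(f"randomisation {self.id!r} has no arm {arm_id!r}")

    def validate(self) -> None:
        ids = [a.id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise DesignError(f"randomisation {self.id!r}: duplicate arm ids")
        _ = self.control
        if self.status == "open" and len(self.arms) < 2:
            raise DesignError(f"randomisation {self.id!r}: an open randomisation needs >=2 arms")

    def copy(self) -> "Randomisation":
        return Randomisation(self.id, self.position, list(self.arms), self.status, self.fixed_delivery)


@dataclass
class Stage:
    """A period with a constant randomisation scheme."""

    index: int
    scheme: list[Randomisation]
    trigger: str = "initial"
    start_time: float = 0.0  # cumulative patients randomised at stage start

    def open_randomisations(self) -> list[Randomisation]:
        return sorted((r for r in self.scheme if r.status == "open"), key=lambda r: r.position)

    def randomisation(self, rand_id: str) -> Randomisation:
        for r in self.scheme:
            if r.id == rand_id:
                return r
        raise DesignError(f"no randomisation {rand_id!r} in stage {self.index}")

    def label(self) -> str:
        parts = []
        for r in self.open_randomisations():
            arm_ids = [a.id for a in r.research_arms] + [r.control.id]
            parts.append("(" + " vs ".join(arm_ids) + ")")
        return " x ".join(parts) if parts else "(closed)"

    def scheme_signature(self) -> tuple:
        return tuple(
            (r.id, r.status, tuple((a.id, a.role, a.weight) for a in r.arms))
            for r in sorted(self.scheme, key=lambda r: r.position)
        )


@dataclass(frozen=True)
class Adaptation:
    """A scheme change: stopping, adding or retiring interventions.

    ``time`` is expressed as cumulative patients randomised.  ``target`` is an
    intervention id for stops / drop_completed, a randomisation id for
    add_intervention, and a fresh randomisation id for add_randomisation.
    """

    kind: str
    target: str
    time: float = 0.0
    new_arm: str | None = None  # for add_intervention
    arms: tuple | None = None  # for add_randomisation: ((id, role, weight), ...)
    weight: Fraction = Fraction(1)

    def __post_init__(self):
        if self.kind not in ADAPTATION_KINDS:
            raise DesignError(f"unknown adaptation kind {self.kind!r}")


@dataclass
class TrialDesign:
    """A factorial-MAMS design: randomisation trajectory plus planning inputs."""

    stages: list[Stage]
    targets: dict[str, int]  # comparison id -> patients required
    default_target: int | None = None
    stratification_factors: dict[str, list] = field(default_factory=dict)
    accrual_rate: float = 1.0
    planned_adaptations: list[Adaptation] = field(default_factory=list)
    eligibility_fractions: dict[str, Fraction] = field(default_factory=dict)
    deliver_control_after_stop: bool = True

    @property
    def current_stage(self) -> Stage:
        return self.stages[-1]

    def comparison_ids(self, include_planned: bool = True) -> list[str]:
        """All pairwise research-vs-control comparison ids in trajectory order."""
        ids: list[str] = []
        for stage in self.stages:
            for r in sorted(stage.scheme, key=lambda x: x.position):
                for arm in r.research_arms:
                    cid = comparison_id(arm.id, r.control.id)
                    if cid not in ids:
                        ids.append(cid)
        if include_planned:
            for ad in self.planned_adaptations:
                if ad.kind == "add_intervention":
                    r = self.current_stage.randomisation(ad.target)
                    cid = comparison_id(ad.new_arm, r.control.id)
                    if cid not in ids:
                        ids.append(cid)
                elif ad.kind == "add_randomisation" and ad.arms:
                    ctrl = [a for a in ad.arms if a[1] == CONTROL][0][0]
                    for a in ad.arms:
                        if a[1] == RESEARCH:
                            cid = comparison_id(a[0], ctrl)
                            if cid not in ids:
                                ids.append(cid)
        return ids

    def target_for(self, cid: str) -> int:
        if cid in self.targets:
            return self.targets[cid]
        if self.default_target is not None:
            return self.default_target
        raise DesignError(f"no sample-size target for comparison {cid!r}")

    def randomisation_of_arm(self, arm_id: str, stage: Stage | None = None) -> Randomisation:
        stage = stage or self.current_stage
        for r in stage.scheme:
            if any(a.id == arm_id for a in r.arms):
                return r
        raise DesignError(f"no arm {arm_id!r} in stage {stage.index}")

    def validate(self) -> None:
        if not self.stages:
            raise DesignError("design has no stages")
        for r in self.current_stage.scheme:
            r.validate()
        idx = [s.index for s in self.stages]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise DesignError("stage indices must be strictly increasing")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.scheme_signature() == b.scheme_signature():
                raise DesignError(f"stages {a.index} and {b.index} have identical schemes")
        all_ids = [a.id for s in [self.current_stage] for r in s.scheme for a in r.arms]
        if len(set(all_ids)) != len(all_ids):
            raise DesignError("intervention ids must be unique within the trial")
        for cid, t in self.targets.items():
            if t <= 0:
                raise DesignError(f"target for {cid!r} must be positive")


def comparison_id(research_arm: str, control_arm: str) -> str:
    return f"{research_arm}-vs-{control_arm}"


def make_factorial_design(
    randomisation_specs: Sequence[dict],
    targets: int | dict[str, int],
    factors: dict[str, list] | None = None,
    accrual_rate: float = 1.0,
    planned_adaptations: Iterable[Adaptation] = (),
    eligibility_fractions: dict[str, Fraction] | None = None,
) -> TrialDesign:
    """Build the initial full-cross factorial design.

    Each randomisation spec is ``{"id": ..., "arms": [{"id", "role", "weight"}]}``.
    ``targets`` is a single per-comparison patient target or a mapping from
    comparison id (``"A1-vs-A0"``) to target.
    """
    if not randomisation_specs:
        raise DesignError("at least one randomisation is required")
    rands: list[Randomisation] = []
    for pos, spec in enumerate(randomisation_specs, start=1):
        arms = [
            Arm(a["id"], a.get("role", RESEARCH), Fraction(a.get("weight", 1)))
            for a in spec["arms"]
        ]
        r = Randomisation(spec["id"], pos, arms)
        r.validate()
        rands.append(r)
    if len({r.id for r in rands}) != len(rands):
        raise DesignError("duplicate randomisation ids")
    stage1 = Stage(index=1, scheme=rands, trigger="initial", start_time=0.0)
    if isinstance(targets, dict):
        tgt, default = dict(targets), None
    else:
        tgt, default = {}, int(targets)
    design = TrialDesign(
        stages=[stage1],
        targets=tgt,
        default_target=default,
        stratification_factors=dict(factors or {}),
        accrual_rate=accrual_rate,
        planned_adaptations=sorted(planned_adaptations, key=lambda a: a.time),
        eligibility_fractions={k: Fraction(v) for k, v in (eligibility_fractions or {}).items()},
    )
    design.validate()
    return design


def enumerate_arms(stage: Stage) -> list[tuple[str, ...]]:
    """Cross product of the open randomisations' arms, in deterministic order.

    Order is lexicographic by randomisation position, then arm id.
    """
    open_rands = stage.open_randomisations()
    if not open_rands:
        raise DesignError(f"stage {stage.index} has no open randomisation")
    arm_lists = [sorted((a.id for a in r.arms)) for r in open_rands]
    return list(itertools.product(*arm_lists))


def apply_adaptation(design: TrialDesign, adaptation: Adaptation, time: float | None = None) -> TrialDesign:
    """Return a new design with the adaptation applied and a new Stage appended."""
    design = copy.deepcopy(design)
    prev = design.current_stage
    scheme = [r.copy() for r in prev.scheme]
    when = adaptation.time if time is None else time
    kind, target = adaptation.kind, adaptation.target

    if kind in ("stop_lack_of_benefit", "stop_efficacy", "drop_completed"):
        rand = None
        for r in scheme:
            if any(a.id == target for a in r.arms):
                rand = r
        if rand is None:
            raise DesignError(f"cannot stop {target!r}: no such intervention")
        if rand.status != "open":
            raise DesignError(f"cannot stop {target!r}: randomisation {rand.id!r} is discontinued")
        arm = rand.arm(target)
        if arm.role == CONTROL:
            raise DesignError(f"cannot stop control arm {target!r}")
        if len(rand.arms) == 2:
            # stopping the only research arm discontinues the whole randomisation
            rand.status = "discontinued"
            if kind == "stop_efficacy":
                rand.fixed_delivery = target  # adopt_winner handled by caller policy
            elif design.deliver_control_after_stop:
                rand.fixed_delivery = rand.control.id
            else:
                rand.fixed_delivery = None
        else:
            rand.arms = [a for a in rand.arms if a.id != target]
    elif kind == "add_randomisation":
        if any(r.id == target for r in scheme):
            raise DesignError(f"randomisation id {target!r} already exists")
        if not adaptation.arms:
            raise DesignError("add_randomisation requires an arm specification")
        arms = [Arm(a[0], a[1], Fraction(a[2]) if len(a) > 2 else Fraction(1)) for a in adaptation.arms]
        existing = {a.id for r in scheme for a in r.arms}
        if existing & {a.id for a in arms}:
            raise DesignError("duplicate intervention id in added randomisation")
        new_rand = Randomisation(target, max(r.position for r in scheme) + 1, arms)
        new_rand.validate()
        if len(new_rand.arms) != 2:
            raise DesignError("an added randomisation must be 2-way (research vs control)")
        scheme.append(new_rand)
    elif kind == "add_intervention":
        rand = next((r for r in scheme if r.id == target), None)
        if rand is None:
            raise DesignError(f"no randomisation {target!r} to add to")
        if rand.status != "open":
            raise DesignError(f"cannot add to discontinued randomisation {target!r}")
        if adaptation.new_arm is None:
            raise DesignError("add_intervention requires new_arm")
        existing = {a.id for r in scheme for a in r.arms}
        if adaptation.new_arm in existing:
            raise DesignError(f"duplicate intervention id {adaptation.new_arm!r}")
        rand.arms = rand.arms + [Arm(adaptation.new_arm, RESEARCH, Fraction(adaptation.weight))]
    else:  # pragma: no cover - guarded in Adaptation
        raise DesignError(f"unknown adaptation kind {kind!r}")

    new_stage = Stage(index=prev.index + 1, scheme=scheme,
                      trigger=f"{kind}:{target}", start_time=when)
    design.stages.append(new_stage)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Config round-trip


def _design_to_dict(design: TrialDesign) -> dict:
    stage1 = design.stages[0]
    return {
        "randomisations": [
            {
                "id": r.id,
                "arms": [
                    {"id": a.id, "role": a.role, "weight": str(a.weight)} for a in r.arms
                ],
            }
            for r in sorted(stage1.scheme, key=lambda r: r.position)
        ],
        "targets": design.targets if design.targets else design.default_target,
        "stratification_factors": design.stratification_factors,
        "accrual_rate": float(design.accrual_rate),
        "adaptations": [
            {
                "kind": a.kind,
                "target": a.target,
                "time": float(a.time),
                **({"new_arm": a.new_arm} if a.new_arm else {}),
                **({"arms": [list(x) for x in a.arms]} if a.arms else {}),
            }
            for a in design.planned_adaptations
        ],
        "eligibility_fractions": {k: str(v) for k, v in design.eligibility_fractions.items()},
    }


def _design_from_dict(cfg: dict) -> TrialDesign:
    errors = []
    if not cfg.get("randomisations"):
        errors.append("config must list at least one randomisation")
    if cfg.get("targets") in (None, {}):
        errors.append("config must give per-comparison 'targets' (mapping or single number)")
    if errors:
        raise DesignError("; ".join(errors))
    adaptations = []
    for a in cfg.get("adaptations", []):
        adaptations.append(
            Adaptation(
                kind=a["kind"],
                target=a["target"],
                time=float(a.get("time", 0)),
                new_arm=a.get("new_arm"),
                arms=tuple(tuple(x) for x in a["arms"]) if a.get("arms") else None,
                weight=Fraction(a.get("weight", 1)),
            )
        )
    targets = cfg["targets"]
    if isinstance(targets, dict):
        targets = {k: int(v) for k, v in targets.items()}
    else:
        targets = int(targets)
    specs = [
        {
            "id": r["id"],
            "arms": [
                {
                    "id": a["id"],
                    "role": a.get("role", RESEARCH),
                    "weight": Fraction(str(a.get("weight", 1))),
                }
                for a in r["arms"]
            ],
        }
        for r in cfg["randomisations"]
    ]
    return make_factorial_design(
        specs,
        targets,
        factors=cfg.get("stratification_factors") or {},
        accrual_rate=float(cfg.get("accrual_rate", 1.0)),
        planned_adaptations=adaptations,
        eligibility_fractions={
            k: Fraction(str(v)) for k, v in (cfg.get("eligibility_fractions") or {}).items()
        },
    )


def load_design(path_or_dict) -> TrialDesign:
    """Load a design from a YAML/JSON file path, file object or dict."""
    if isinstance(path_or_dict, dict):
        return _design_from_dict(path_or_dict)
    if hasattr(path_or_dict, "read"):
        return _design_from_dict(yaml.safe_load(path_or_dict))
    with open(path_or_dict) as fh:
        return _design_from_dict(yaml.safe_load(fh))


def dump_design(design: TrialDesign, path=None, fmt: str = "yaml"):
    """Serialise a design's initial scheme + planned adaptations."""
    d = _design_to_dict(design)
    text = json.dumps(d, indent=2) if fmt == "json" else yaml.safe_dump(d, sort_keys=False)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return path
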