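"""Sequential stratified permuted-block randomisation.

Each randomisation is performed in position order, stratified by the trial's
baseline stratification factors and by the patient's allocation in every
*earlier* randomisation, with a ``not-randomised`` level for patients who did
not enter an earlier randomisation (ineligible, non-consenting, or recruited
after it was discontinued).  Within each stratum, assignments are drawn from
permuted blocks whose size is a randomly chosen multiple of the number of
active arms, so imbalance is bounded by the contents of the single open block.

Adaptations follow the bookkeeping rules for sequential schemes: adding an
arm (or dropping one from a >=3-way randomisation) closes that randomisation's
open blocks and starts fresh blocks over the new arm set, while later
randomisations keep their existing blocks — patients allocated to a new arm
simply open new strata downstream.  Dropping the only research arm of a 2-way
randomisation discontinues it: subsequent patients receive a scheme-fixed
delivery (the control by default) and count as ``not-randomised`` in
downstream strata.

Patients eligible for only a reduced subset of a multi-way randomisation's
arms are randomised within block families specific to that subset, and their
records carry the subset so the analysis can restrict them to comparisons
their subset covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd, lcm

import numpy as np
import pandas as pd

from .design import Adaptation, DesignError, Randomisation, TrialDesign

__all__ = [
    "AllocationRecord",
    "Block",
    "Randomiser",
    "NoEligibleRandomisationError",
    "adapt_randomiser",
    "imbalance_report",
]

NOT_RANDOMISED = "not-randomised"


class NoEligibleRandomisationError(DesignError):
    """The patient is eligible for no randomisation and cannot be recruited."""


@dataclass
class AllocationRecord:
    patient_id: int
    randomisation_id: str
    assignment: str | None  # arm id received (randomised or fixed), None if nothing
    mechanism: str  # randomised | not-eligible | not-consented | scheme-fixed
    stratum: tuple
    block_id: int | None
    sequence: int
    stage_index: int
    time: float
    eligible_subset: frozenset | None = None  # None => eligible for all active arms


@dataclass
class Block:
    block_id: int
    randomisation_id: str
    stratum: tuple
    size: int
    remaining: list[str] = field(default_factory=list)

    @property
    def exhausted(self) -> bool:
        return not self.remaining

    def draw(self) -> str:
        return self.remaining.pop()


def _block_composition(arms, multiple: int) -> list[str]:
    """Arm ids for one block: weights reduced to smallest integers x multiple."""
    weights = [Fraction(a.weight) for a in arms]
    denom = lcm(*(w.denominator for w in weights))
    ints = [int(w * denom) for w in weights]
    g = gcd(*ints)
    ints = [i // g for i in ints]
    out: list[str] = []
    for arm, count in zip(arms, ints):
        out.extend([arm.id] * (count * multiple))
    return out


class Randomiser:
    """Stateful sequential stratified block randomiser for one trial run."""

    def __init__(
        self,
        design: TrialDesign,
        rng: np.random.Generator,
        block_multiples: tuple[int, ...] = (1, 2),
    ):
        self.design = design
        self.rng = rng
        self.block_multiples = tuple(block_multiples)
        self.blocks: dict[tuple, Block] = {}  # open block per (rand, epoch, subset, stratum)
        self.all_blocks: list[Block] = []  # every block ever opened (audit)
        self.epoch: dict[str, int] = {}
        self.records: list[AllocationRecord] = []
        self._block_counter = 0
        self._sequence = 0

    # -- assignment -------------------------------------------------------
    def randomise_patient(self, patient, stage_index: int | None = None, time: float = 0.0) -> list[AllocationRecord]:
        """Process all randomisations for one patient, in position order.

        ``patient`` needs ``id`` and may carry ``eligibility`` (per-arm bool
        mapping, default eligible), ``consent`` (per-randomisation bool,
        default consenting) and ``factors`` (stratification factor levels).
        """
        stage = self.design.current_stage
        stage_index = stage.index if stage_index is None else stage_index
        eligibility = getattr(patient, "eligibility", None) or {}
        consent = getattr(patient, "consent", None) or {}
        factors = getattr(patient, "factors", None) or {}
        base_stratum = tuple(factors[k] for k in sorted(self.design.stratification_factors))

        records: list[AllocationRecord] = []
        earlier_levels: list[str] = []
        rands = sorted(stage.scheme, key=lambda r: r.position)
        for rand in rands:
            stratum = base_stratum + tuple(earlier_levels)
            rec = self._one_randomisation(patient, rand, stratum, stage_index, time, eligibility, consent)
            records.append(rec)
            earlier_levels.append(rec.assignment if rec.mechanism == "randomised" else NOT_RANDOMISED)

        if not any(r.mechanism == "randomised" for r in records):
            raise NoEligibleRandomisationError(
                f"patient {patient.id} is eligible for no randomisation "
                f"({[(r.randomisation_id, r.mechanism) for r in records]})"
            )
        self.records.extend(records)
        return records

    def _one_randomisation(self, patient, rand: Randomisation, stratum, stage_index, time, eligibility, consent):
        self._sequence += 1
        common = dict(
            patient_id=patient.id,
            randomisation_id=rand.id,
            stratum=stratum,
            block_id=None,
            sequence=self._sequence,
            stage_index=stage_index,
            time=time,
        )
        if rand.status != "open":
            return AllocationRecord(assignment=rand.fixed_delivery, mechanism="scheme-fixed", **common)
        if not consent.get(rand.id, True):
            return AllocationRecord(assignment=None, mechanism="not-consented", **common)
        eligible_arms = [a for a in rand.arms if eligibility.get(a.id, True)]
        if len(eligible_arms) < 2:
            # delivered the control if it is tolerated, else nothing
            delivered = rand.control.id if eligibility.get(rand.control.id, True) else None
            return AllocationRecord(assignment=delivered, mechanism="not-eligible", **common)
        subset = frozenset(a.id for a in eligible_arms)
        full = subset == frozenset(a.id for a in rand.arms)
        block = self._get_block(rand, subset, stratum, eligible_arms)
        arm = block.draw()
        return AllocationRecord(
            assignment=arm,
            mechanism="randomised",
            eligible_subset=None if full else subset,
            **{**common, "block_id": block.block_id},
        )

    def _get_block(self, rand: Randomisation, subset: frozenset, stratum: tuple, arms) -> Block:
        key = (rand.id, self.epoch.get(rand.id, 0), subset, stratum)
        block = self.blocks.get(key)
        if block is None or block.exhausted:
            multiple = int(self.rng.choice(self.block_multiples))
            contents = _block_composition(arms, multiple)
            order = self.rng.permutation(len(contents))
            self._block_counter += 1
            block = Block(
                block_id=self._block_counter,
                randomisation_id=rand.id,
                stratum=stratum,
                size=len(contents),
                remaining=[contents[i] for i in order],
            )
            self.blocks[key] = block
            self.all_blocks.append(block)
        return block

    # -- adaptation -------------------------------------------------------
    def bind(self, design: TrialDesign) -> None:
        """Point the randomiser at the post-adaptation design."""
        self.design = design

    def adapt(self, adaptation: Adaptation) -> None:
        """Apply the block/stratum bookkeeping for an adaptation.

        The adaptation must already be applied to the bound design.
        """
        kind, target = adaptation.kind, adaptation.target
        stage = self.design.current_stage
        if kind == "add_randomisation":
            return  # appended last in sequence; blocks created lazily
        if kind == "add_intervention":
            self.epoch[target] = self.epoch.get(target, 0) + 1
            return
        if kind in ("stop_lack_of_benefit", "stop_efficacy", "drop_completed"):
            # the arm is already removed from the current scheme; find its
            # randomisation in the pre-adaptation stage
            prev = self.design.stages[-2] if len(self.design.stages) >= 2 else stage
            rand_prev = next((r for r in prev.scheme if any(a.id == target for a in r.arms)), None)
            if rand_prev is None:
                raise DesignError(f"stopped arm {target!r} not found in the previous stage")
            rand_now = stage.randomisation(rand_prev.id)
            if rand_now.status == "open":
                # >=3-way drop: close blocks, reopen over the remaining arms;
                # later randomisations keep their blocks in ongoing strata
                self.epoch[rand_now.id] = self.epoch.get(rand_now.id, 0) + 1
            # 2-way drop: randomisation discontinued; nothing to close — future
            # patients get scheme-fixed delivery and downstream strata use the
            # not-randomised level
            return
        raise DesignError(f"unknown adaptation kind {kind!r}")

    # -- reporting --------------------------------------------------------
    def allocation_log(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "patient_id": r.patient_id,
                    "time": r.time,
                    "stage": r.stage_index,
                    "randomisation": r.randomisation_id,
                    "stratum": "|".join(map(str, r.stratum)),
                    "block": r.block_id,
                    "assignment": r.assignment,
                    "mechanism": r.mechanism,
                }
                for r in self.records
            ]
        )


def adapt_randomiser(randomiser: Randomiser, adaptation: Adaptation, design: TrialDesign | None = None) -> Randomiser:
    """Functional wrapper: bind the adapted design and update block state."""
    if design is not None:
        randomiser.bind(design)
    randomiser.adapt(adaptation)
    return randomiser


def imbalance_report(randomiser: Randomiser) -> pd.DataFrame:
    """Arm counts per (randomisation, stratum) over randomised records only.

    Includes the maximum pairwise count difference within each stratum.
    """
    rows: dict[tuple, dict[str, int]] = {}
    for rec in randomiser.records:
        if rec.mechanism != "randomised":
            continue
        key = (rec.randomisation_id, rec.stratum)
        rows.setdefault(key, {})
        rows[key][rec.assignment] = rows[key].get(rec.assignment, 0) + 1
    recs = []
    for (rand_id, stratum), counts in sorted(rows.items()):
        vals = list(counts.values())
        recs.append(
            {
                "randomisation": rand_id,
                "stratum": "|".join(map(str, stratum)),
                "counts": dict(sorted(counts.items())),
                "max_difference": (max(vals) - min(vals)) if len(vals) > 1 else 0,
            }
        )
    return pd.DataFrame.from_records(recs, columns=["randomisation", "stratum", "counts", "max_difference"])
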