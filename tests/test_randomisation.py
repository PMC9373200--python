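"""Sequential stratified block randomisation: balance, strata, adaptations."""

import numpy as np
import pytest

from fmams import (
    Randomiser,
    adapt_randomiser,
    apply_adaptation,
    imbalance_report,
    make_factorial_design,
)
from fmams.design import Adaptation
from fmams.outcomes import PatientProfile
from fmams.randomisation import NOT_RANDOMISED, NoEligibleRandomisationError


def patients(n, start=1, **kwargs):
    return [PatientProfile(id=i, arrival_time=float(i), **kwargs) for i in range(start, start + n)]


def test_standard_patient_gets_one_arm_per_randomisation(design_2x2):
    rng = np.random.default_rng(1)
    r = Randomiser(design_2x2, rng)
    recs = r.randomise_patient(patients(1)[0])
    assert [x.randomisation_id for x in recs] == ["A", "B"]
    assert recs[0].assignment in ("A0", "A1")
    assert recs[1].assignment in ("B0", "B1")
    assert all(x.mechanism == "randomised" for x in recs)
    # the B stratum records the earlier A allocation
    assert recs[1].stratum == (recs[0].assignment,)


def test_ineligible_for_a1_gets_a0_and_enters_b(design_2x2):
    rng = np.random.default_rng(2)
    r = Randomiser(design_2x2, rng)
    p = patients(1, eligibility={"A1": False})[0]
    recs = r.randomise_patient(p)
    assert recs[0].mechanism == "not-eligible"
    assert recs[0].assignment == "A0"  # delivered, not randomised
    assert recs[1].mechanism == "randomised"
    assert recs[1].stratum == (NOT_RANDOMISED,)


def test_patient_eligible_nowhere_is_rejected(design_2x2):
    rng = np.random.default_rng(3)
    r = Randomiser(design_2x2, rng)
    p = patients(1, eligibility={"A1": False, "B1": False})[0]
    with pytest.raises(NoEligibleRandomisationError):
        r.randomise_patient(p)


def test_reduced_set_randomisation_draws_within_subset(design_2x2):
    design = apply_adaptation(design_2x2, Adaptation("add_intervention", "A", new_arm="A2"))
    rng = np.random.default_rng(4)
    r = Randomiser(design, rng)
    for p in patients(30, eligibility={"A1": False}):
        recs = r.randomise_patient(p)
        assert recs[0].mechanism == "randomised"
        assert recs[0].assignment in ("A0", "A2")
        assert recs[0].eligible_subset == frozenset({"A0", "A2"})


def test_completed_blocks_are_exactly_balanced(design_2x2):
    rng = np.random.default_rng(5)
    r = Randomiser(design_2x2, rng, block_multiples=(2,))
    for p in patients(400):
        r.randomise_patient(p)
    by_block: dict[int, list[str]] = {}
    for rec in r.records:
        if rec.mechanism == "randomised":
            by_block.setdefault(rec.block_id, []).append(rec.assignment)
    sizes = {b.block_id: b.size for b in r.all_blocks}
    complete = {bid: arms for bid, arms in by_block.items() if len(arms) == sizes[bid]}
    assert complete, "some blocks should be complete after 400 patients"
    for arms in complete.values():
        counts = {a: arms.count(a) for a in set(arms)}
        assert len(set(counts.values())) == 1  # each arm b/k times


@pytest.mark.parametrize("seed", range(5))
def test_within_stratum_imbalance_bounded_by_block_quota(seed):
    """With blocks of size 2k the arm-count gap never exceeds b/k = 2."""
    design = make_factorial_design(
        [
            {"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]},
            {"id": "B", "arms": [{"id": "B0", "role": "control"}, {"id": "B1", "role": "research"}]},
        ],
        10_000,
    )
    rng = np.random.default_rng(seed)
    r = Randomiser(design, rng, block_multiples=(2,))
    for i, p in enumerate(patients(1000), start=1):
        r.randomise_patient(p)
        if i % 250 == 0:
            report = imbalance_report(r)
            assert (report["max_difference"] <= 2).all()


def test_identical_seed_reproduces_allocation_log(design_table2):
    logs = []
    for _ in range(2):
        r = Randomiser(design_table2, np.random.default_rng(99))
        for p in patients(200):
            r.randomise_patient(p)
        logs.append(r.allocation_log())
    assert logs[0].equals(logs[1])


def test_add_intervention_closes_existing_blocks(design_2x2):
    rng = np.random.default_rng(7)
    r = Randomiser(design_2x2, rng, block_multiples=(2,))
    for p in patients(101):
        r.randomise_patient(p)
    pre_blocks = {rec.block_id for rec in r.records if rec.randomisation_id == "A"}
    adaptation = Adaptation("add_intervention", "A", new_arm="A2")
    design = apply_adaptation(design_2x2, adaptation)
    adapt_randomiser(r, adaptation, design)
    post = []
    for p in patients(120, start=200):
        post.extend(r.randomise_patient(p))
    post_a = [rec for rec in post if rec.randomisation_id == "A"]
    # no assignment ever issued from a block opened before the adaptation
    assert not any(rec.block_id in pre_blocks for rec in post_a)
    assert {rec.assignment for rec in post_a} == {"A0", "A1", "A2"}
    # B keeps its existing strata/blocks for patients not on the new arm,
    # and gains new strata for patients allocated to A2
    strata_b = {rec.stratum for rec in post if rec.randomisation_id == "B"}
    assert ("A2",) in strata_b and ("A0",) in strata_b


def test_drop_from_two_way_fixes_delivery_and_downstream_stratum():
    specs = [
        {"id": r, "arms": [{"id": f"{r}0", "role": "control"}, {"id": f"{r}1", "role": "research"}]}
        for r in ("A", "B", "C")
    ]
    design = make_factorial_design(specs, 1000)
    rng = np.random.default_rng(8)
    r = Randomiser(design, rng)
    for p in patients(20):
        r.randomise_patient(p)
    adapted = apply_adaptation(design, Adaptation("stop_lack_of_benefit", "B1"))
    adapt_randomiser(r, Adaptation("stop_lack_of_benefit", "B1"), adapted)
    recs = r.randomise_patient(patients(1, start=50)[0])
    rec_b = next(x for x in recs if x.randomisation_id == "B")
    assert rec_b.mechanism == "scheme-fixed"
    assert rec_b.assignment == "B0"
    rec_c = next(x for x in recs if x.randomisation_id == "C")
    assert rec_c.stratum[1] == NOT_RANDOMISED  # (A level, B level)


def test_drop_from_three_way_reopens_blocks_over_remaining_arms(design_2x2):
    design = apply_adaptation(design_2x2, Adaptation("add_intervention", "A", new_arm="A2"))
    rng = np.random.default_rng(9)
    r = Randomiser(design, rng)
    for p in patients(60):
        r.randomise_patient(p)
    # open (part-used) B blocks per stratum before the adaptation
    open_b = {
        key[3]: blk.block_id
        for key, blk in r.blocks.items()
        if key[0] == "B" and blk.remaining
    }
    adapted = apply_adaptation(design, Adaptation("stop_lack_of_benefit", "A1"))
    adapt_randomiser(r, Adaptation("stop_lack_of_benefit", "A1"), adapted)
    assert r.epoch.get("A", 0) == 1  # A blocks closed, reopened over {A0, A2}
    assert r.epoch.get("B", 0) == 0  # B keeps its block families
    recs = []
    for p in patients(60, start=100):
        recs.extend(r.randomise_patient(p))
    a_recs = [x for x in recs if x.randomisation_id == "A"]
    assert {x.assignment for x in a_recs} == {"A0", "A2"}
    # later randomisation B continues assigning patients to its existing
    # open blocks in the ongoing strata
    for stratum, bid in open_b.items():
        if stratum == ("A1",):
            continue  # stratum no longer receives new patients
        first = next(
            x for x in recs if x.randomisation_id == "B" and x.stratum == stratum
        )
        assert first.block_id == bid
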