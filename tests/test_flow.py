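"""Deterministic patient-flow planner: golden tables, oracle, invariants."""

from fractions import Fraction

import pytest

from fmams import make_factorial_design, plan_flow, reporting_milestones, timeline_export
from fmams.design import Adaptation, comparison_id


def test_adapted_design_flow_table(design_table2):
    flow = plan_flow(design_table2)
    assert [r.n_randomised for r in flow.rows] == [1500, 1500, 750, 1500]
    contrib = [
        {cid: int(v) for cid, v in row.contributions.items() if v > 0} for row in flow.rows
    ]
    assert contrib == [
        {"A1-vs-A0": 1500, "B1-vs-B0": 1500},
        {"A1-vs-A0": 1000, "B1-vs-B0": 1500, "A2-vs-A0": 1000},
        {"A1-vs-A0": 500, "A2-vs-A0": 500},
        {"A2-vs-A0": 1500},
    ]
    assert flow.total_randomised == 5250
    assert {cid: int(v) for cid, v in flow.totals.items()} == {
        "A1-vs-A0": 3000,
        "B1-vs-B0": 3000,
        "A2-vs-A0": 3000,
    }


def test_unadapted_design_totals(design_2x2):
    flow = plan_flow(design_2x2)
    assert flow.total_randomised == 3000
    assert all(int(v) == 3000 for v in flow.totals.values())
    assert reporting_milestones(flow) == {"A1-vs-A0": 3000, "B1-vs-B0": 3000}


def test_early_stop_reduces_total_to_4500(specs_2x2):
    design = make_factorial_design(
        specs_2x2,
        3000,
        planned_adaptations=[
            Adaptation("add_intervention", "A", 1500, new_arm="A2"),
            Adaptation("stop_lack_of_benefit", "A1", 1500),
        ],
    )
    flow = plan_flow(design)
    assert flow.total_randomised == 4500
    assert int(flow.totals["A2-vs-A0"]) == 3000
    assert int(flow.totals["B1-vs-B0"]) == 3000


def test_reporting_milestones_adapted(design_table2):
    ms = reporting_milestones(plan_flow(design_table2))
    assert ms["B1-vs-B0"] == 3000
    assert ms["A1-vs-A0"] == 3750  # 750 more than the original end point
    assert ms["A2-vs-A0"] == 5250  # a further 1500


def test_single_two_arm_design_milestone_is_target():
    design = make_factorial_design(
        [{"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]}],
        800,
    )
    assert reporting_milestones(plan_flow(design)) == {"A1-vs-A0": 800}


def test_timeline_segments(design_table2, design_2x2, tmp_path):
    flow = plan_flow(design_table2)
    df = timeline_export(flow, 100.0, tmp_path / "timeline.csv")
    ends = dict(zip(df["comparison"], df["end"]))
    assert ends == {"B1-vs-B0": 30.0, "A1-vs-A0": 37.5, "A2-vs-A0": 52.5}
    assert (tmp_path / "timeline.csv").exists()
    df0 = timeline_export(plan_flow(design_2x2), 100.0)
    assert set(df0["end"]) == {30.0}


def test_timeline_rejects_zero_rate(design_2x2):
    import pytest as _pytest

    from fmams.design import DesignError

    with _pytest.raises(DesignError):
        timeline_export(plan_flow(design_2x2), 0.0)


def test_unreachable_target_is_flagged(specs_2x2):
    # stopping A1 with no replacement makes A1-vs-A0 unreachable
    design = make_factorial_design(
        specs_2x2, 3000, planned_adaptations=[Adaptation("stop_lack_of_benefit", "A1", 1000)]
    )
    flow = plan_flow(design)
    assert flow.total_randomised == 3000  # B still completes
    assert int(flow.totals["B1-vs-B0"]) == 3000
    assert "A1-vs-A0" not in reporting_milestones(flow)


# ---------------------------------------------------------------------------
# Brute-force per-patient oracle


def brute_force_flow(specs, target, adaptations):
    """Round-robin per-patient counting simulation (independent oracle).

    Allocates patients deterministically in rotation within each open
    randomisation (equal weights) and counts actual contributions; applies
    the same completion/drop rules one patient at a time.
    """
    arms = {s["id"]: [a["id"] for a in s["arms"]] for s in specs}
    controls = {s["id"]: next(a["id"] for a in s["arms"] if a["role"] == "control") for s in specs}
    order = [s["id"] for s in specs]
    open_rand = {r: True for r in order}
    cursor = {r: 0 for r in order}
    comps = {}
    for r in order:
        for a in arms[r]:
            if a != controls[r]:
                comps[comparison_id(a, controls[r])] = {"rand": r, "arm": a, "count": 0, "open": True}
    pending = sorted(adaptations, key=lambda x: x[0])
    total = 0
    while any(c["open"] for c in comps.values()) or pending:
        while pending and pending[0][0] <= total:
            _, kind, rand_id, arm = pending.pop(0)
            if kind == "add":
                arms[rand_id].append(arm)
                cursor[rand_id] = 0
                comps[comparison_id(arm, controls[rand_id])] = {
                    "rand": rand_id, "arm": arm, "count": 0, "open": True,
                }
            else:  # stop
                arms[rand_id].remove(arm)
                cursor[rand_id] = 0
                comps[comparison_id(arm, controls[rand_id])]["open"] = False
                if len(arms[rand_id]) < 2:
                    open_rand[rand_id] = False
        if not any(c["open"] for c in comps.values()):
            break
        total += 1
        for r in order:
            if not open_rand[r]:
                continue
            assigned = arms[r][cursor[r] % len(arms[r])]
            cursor[r] += 1
            for cid, c in comps.items():
                if c["open"] and c["rand"] == r and assigned in (c["arm"], controls[r]):
                    c["count"] += 1
        for cid, c in list(comps.items()):
            if c["open"] and c["count"] >= target:
                c["open"] = False
                r = c["rand"]
                arms[r].remove(c["arm"])
                cursor[r] = 0
                if len(arms[r]) < 2 or not any(
                    x["open"] for x in comps.values() if x["rand"] == r
                ):
                    open_rand[r] = False
    return total


CASES = [
    # (n randomisations, target, adaptations [(time, kind, rand, arm)])
    (1, 120, []),
    (2, 120, []),
    (2, 120, [(60, "add", "A", "A2")]),
    (2, 120, [(60, "add", "A", "A2"), (60, "stop", "A", "A1")]),
    (3, 60, []),
    (2, 120, [(30, "stop", "B", "B1")]),
]


@pytest.mark.parametrize("n_rand,target,adaptations", CASES)
def test_planner_matches_per_patient_counting_oracle(n_rand, target, adaptations):
    specs = [
        {"id": r, "arms": [{"id": f"{r}0", "role": "control"}, {"id": f"{r}1", "role": "research"}]}
        for r in ("A", "B", "C")[:n_rand]
    ]
    planned = [
        Adaptation("add_intervention", rand, time=t, new_arm=arm)
        if kind == "add"
        else Adaptation("stop_lack_of_benefit", arm, time=t)
        for (t, kind, rand, arm) in adaptations
    ]
    design = make_factorial_design(specs, target, planned_adaptations=planned)
    flow = plan_flow(design)
    assert flow.total_randomised == brute_force_flow(specs, target, adaptations)


def test_conservation_and_rounding(design_table2):
    flow = plan_flow(design_table2)
    assert sum(r.n_randomised for r in flow.rows) == flow.total_randomised
    for cid, total in flow.totals.items():
        assert total == sum(
            (r.contributions.get(cid, Fraction(0)) for r in flow.rows), Fraction(0)
        )
        assert total.denominator == 1  # rounding keeps contributions integral


def test_stopping_earlier_never_increases_total(specs_2x2):
    base = make_factorial_design(
        specs_2x2, 3000,
        planned_adaptations=[Adaptation("add_intervention", "A", 1500, new_arm="A2")],
    )
    totals = [plan_flow(base).total_randomised]
    for stop_at in (2500, 1500, 500):
        d = make_factorial_design(
            specs_2x2, 3000,
            planned_adaptations=[
                Adaptation("add_intervention", "A", 1500, new_arm="A2"),
                Adaptation("stop_lack_of_benefit", "A1", max(stop_at, 1500)),
            ],
        )
        totals.append(plan_flow(d).total_randomised)
    assert totals == sorted(totals, reverse=True) or totals[0] >= max(totals[1:])


def test_eligibility_fraction_scales_accrual(specs_2x2):
    # half the patients enter randomisation B: its comparison needs twice the flow
    design = make_factorial_design(
        specs_2x2, 1000, eligibility_fractions={"B": Fraction(1, 2)}
    )
    flow = plan_flow(design)
    ms = reporting_milestones(flow)
    assert ms["A1-vs-A0"] == 1000
    assert ms["B1-vs-B0"] == 2000
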