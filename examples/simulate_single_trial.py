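"""One simulated factorial-MAMS trial with an interim futility look.

A 2x2 factorial with 600 patients per comparison: A1 is moderately effective
(OR 0.6), B1 is null.  An intermediate outcome (rho = 1) is reviewed at a
single interim (month 3); a research arm whose intermediate z falls below 0
stops for lack of benefit.  Prints the look report, the realised flow and the
final concurrent-control analyses.
"""

from fmams import MonitoringPlan, OutcomeModel, make_factorial_design, run_trial

design = make_factorial_design(
    [
        {"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]},
        {"id": "B", "arms": [{"id": "B0", "role": "control"}, {"id": "B1", "role": "research"}]},
    ],
    targets=600,
    accrual_rate=100,
)
model = OutcomeModel(
    outcome_type="binary",
    baseline=0.35,
    effects={"A1": 0.6},
    intermediate_baseline=0.45,
    intermediate_rho=1.0,
)
plan = MonitoringPlan(
    triggers=[{"type": "calendar", "time": 3.0}],
    efficacy="haybittle_peto",
    futility_bounds=[0.0],
    alpha=0.025,
)

trial = run_trial(design, model, plan, seed=7)
for rep in trial.look_reports:
    print(f"look {rep['look']} at month {rep['time']:.1f}:")
    for cid, z in rep["z_definitive"].items():
        zi = rep["z_intermediate"][cid]
        print(f"  {cid}: z_definitive = {z:+.2f}, z_intermediate = {zi:+.2f}")
    print(f"  decisions: {rep['decisions']}")
print(f"\nrealised stage sizes: {trial.stage_counts}, total n = {trial.total_n}")
for cid, comp in trial.comparisons.items():
    est = "--" if comp.result is None else f"{comp.result.estimate:+.3f}"
    print(
        f"{cid}: decision = {comp.decision}, log-OR = {est}, "
        f"analysed n = {comp.contribution_n}, rejected = {comp.rejected}"
    )
print(
    "\nA positive z means benefit. A futility stop ends randomisation to the"
    "\narm; its patients keep contributing to the other (factorial) comparison."
)
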