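# fmams — factorial multi-arm multi-stage platform trial toolkit

`fmams` simulates and evaluates **factorial-MAMS** designs: platform trials in
which two or more randomisations run concurrently in the same patients
(the factorial element) while each randomisation can gain or lose research
arms at interim analyses (the multi-arm multi-stage element). The combination
is attractive when several interventions could be given together without
interaction — e.g. an antiviral and an immunomodulator for an emerging
infection — but it creates bookkeeping and inference problems that this
package implements end to end:

- **Design model** — randomisations, arms, allocation weights, and the four
  adaptation operators (stop for lack of benefit, stop for efficacy, add a
  randomisation, add an arm to an existing randomisation). Every scheme
  change opens a new *stage*.
- **Deterministic flow planner** — stage-by-stage accounting of patients
  randomised and patients contributing to each pairwise comparison
  `Xi vs X0`, whose expected share per randomised patient is
  `(w_i + w_0) / Σ w` over the active arms (equal k-way allocation: `2/k`),
  plus reporting milestones and calendar timelines.
- **Sequential stratified block randomisation** — each randomisation is
  stratified by the earlier allocations (with a `not-randomised` level),
  permuted blocks bound imbalance, and the block/stratum bookkeeping under
  every adaptation follows the sequential-scheme rules (close and reopen
  blocks when an arm set changes; later randomisations keep their blocks).
- **Outcome simulator** — binary or exponential time-to-event outcomes under
  multiplicative effects (odds/risk ratios, hazard ratios), optional pairwise
  interactions, an intermediate (early) outcome with concordance `ρ`, and an
  optional secular trend in the baseline risk.
- **Interim monitoring** — looks triggered by calendar time or *pooled*
  events across all arms (per-comparison control-arm event counts are
  computed only for DMC reports, never for scheduling); Haybittle-Peto,
  O'Brien-Fleming and alpha-spending efficacy boundaries; one-sided futility
  thresholds on the intermediate outcome.
- **Concurrent-control analysis** — per comparison, only patients randomised
  to one of its two arms during stages when *both* arms were open, analysed
  stage-stratified (Mantel-Haenszel / CMH for binary, stratified Cox for
  time-to-event, benefit-positive z), plus a combined logistic/Cox model with
  one dummy per research intervention and a stage term, and subgroup
  interaction analyses with an inverse-variance homogeneity test.
- **Operating characteristics** — seeded single-trial runs and Monte-Carlo
  replication (type-I error, power, stop probabilities, familywise error,
  expected size and duration).

## Worked example

The package's running illustration is a 2×2 factorial (A1 vs A0 × B1 vs B0),
3000 patients per comparison, equal allocation, where a second research arm
A2 joins randomisation A after 1500 patients:

```python
from fmams import make_factorial_design, plan_flow, reporting_milestones
from fmams.design import Adaptation

design = make_factorial_design(
    [
        {"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]},
        {"id": "B", "arms": [{"id": "B0", "role": "control"}, {"id": "B1", "role": "research"}]},
    ],
    targets=3000,
    accrual_rate=100,
    planned_adaptations=[Adaptation("add_intervention", "A", time=1500, new_arm="A2")],
)
print(plan_flow(design).to_frame().to_string(index=False))
print(reporting_milestones(plan_flow(design)))
```

prints

```
stage                         design  randomised  A1-vs-A0  B1-vs-B0  A2-vs-A0
    1        (A1 vs A0) x (B1 vs B0)        1500    1500.0    1500.0       NaN
    2  (A1 vs A2 vs A0) x (B1 vs B0)        1500    1000.0    1500.0    1000.0
    3               (A1 vs A2 vs A0)         750     500.0       NaN     500.0
    4                     (A2 vs A0)        1500       NaN       NaN    1500.0
total                                        5250    3000.0    3000.0    3000.0
{'A1-vs-A0': 3750, 'B1-vs-B0': 3000, 'A2-vs-A0': 5250}
```

Reading the table: once A becomes a three-way randomisation only 2/3 of its
patients inform each A comparison, so the trial grows from 3000 to 5250
patients. The B comparison still reports on schedule at 3000; A1-vs-A0 needs
750 more patients, and A2-vs-A0 a further 1500. Running the full simulator on
the same design with stopping disabled realises exactly these stage counts for
any seed. The `examples/` directory has one short script per capability
(planning, boundaries, single-trial simulation with an interim look,
operating characteristics, power dilution, stratified randomisation).

A thin CLI wraps the same calls:

```bash
fmams plan --config design.yaml --out flow.csv
fmams simulate --config design.yaml --seed 7 --out run/
fmams oc --config design.yaml --reps 500 --seed 1 --out oc/
fmams boundaries --kind obrien_fleming --looks 2 --alpha 0.05
```

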