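# Methods

## The design problem

A factorial-MAMS trial runs several randomisations concurrently in the same
patients, each comparing one or more research interventions with its own
control, while allowing mid-trial adaptations: ending randomisation to an arm
(for lack of benefit or for efficacy), adding a research arm to an existing
randomisation, or adding a whole new randomisation. The package's central
organising concept is the **stage**: a maximal period during which the
randomisation scheme is constant. Every adaptation — including the implicit
one where a comparison reaches its sample-size target and its arm is retired —
begins a new stage. Stages matter twice: they delimit which control patients
are *concurrent* with each research arm, and they are the stratification unit
of the primary analysis.

The working assumption throughout is the factorial one: interventions in
different randomisations do not interact (interaction multipliers default
to 1), so the "at the margins" analysis of one randomisation can ignore the
others except through the event rate.

## Patient-flow accounting

The planner tracks, per pairwise comparison `Xi vs X0`, the expected number of
contributing patients per patient randomised: `eligibility_fraction ×
(w_i + w_0) / Σ w` over randomisation X's active arms — `2/k` under equal
k-way allocation. All arithmetic is exact (`fractions.Fraction`). Recruitment
advances in segments to the next deterministic event: a scheduled adaptation
(times are expressed as cumulative patients randomised) or a comparison
completion. Completing one comparison of a ≥3-way randomisation retires that
research arm; completing the last comparison retires the randomisation;
recruitment ends when every comparison is complete. A target that can no
longer accrue (all contributing arms stopped) is flagged as unreachable, never
silently dropped.

When a completion point implies a fractional patient count, the segment is
rounded **up** to the next multiple of the least common multiple of the active
accrual fractions' denominators, so stage contribution counts stay integral
and no comparison is under-recruited. The illustrative designs used in the
tests are exact multiples, so rounding never fires there.

The unadapted design produces a single stage: stages are defined by scheme
changes, so a purely administrative interim look does not split the table.

**Accrual is tracked on the allocation-expectation scale in the simulator
too.** `run_trial` uses the same accounting to decide when comparisons
complete and schemes change, which is how trials are planned and monitored in
practice and makes the realised stage boundaries deterministic given the
adaptation schedule — the planner and the simulator agree exactly for any
seed. Realised per-arm counts remain random (bounded by the block quotas) and
are reported per arm.

## Randomisation

Sequential stratified permuted blocks. Randomisations are processed in
position order; the stratum key for randomisation r is (baseline factors…,
allocation in each earlier randomisation), with a `not-randomised` level for
patients who skipped an earlier randomisation (ineligible, non-consenting, or
recruited after it was discontinued). Block sizes are drawn uniformly from a
configurable multiset of multiples of the number of active arms (default
{k, 2k}); a fresh block contains each arm in proportion to its allocation
weight, permuted. Imbalance within a stratum is therefore bounded by the
per-arm quota of the single open block.

Adaptation bookkeeping follows the sequential-scheme rules: adding a
randomisation appends it last (earlier machinery untouched); adding an arm —
or dropping one from a ≥3-way randomisation — closes that randomisation's open
blocks and opens new ones over the new arm set, while later randomisations
keep their existing blocks (patients on a new arm simply open new downstream
strata); dropping the only research arm of a 2-way randomisation discontinues
it, after which patients receive a scheme-fixed delivery (the control by
default, configurable) that is recorded but is **not** a randomised allocation
and never enters comparisons.

Patients eligible for only a subset of a multi-way randomisation's arms are
randomised within block families specific to that subset and flagged so the
analysis restricts them to comparisons inside their subset. Their *later*
randomisation stratum uses the arm they were assigned (not a separate
"reduced-set" level); the convention is a judgement call — the alternative
would multiply strata for little balance gain.

## Outcome model

Binary outcomes: event probability is `expit(logit(p0·trend^t) + Σ log-OR of
received research interventions + Σ log interaction multipliers)`; a
risk-ratio scale is available (`effect_scale="rr"`), in which case effects
multiply the risk directly. Time-to-event outcomes are exponential with
hazard `λ0·trend^t × Π HR`, administratively censored at the follow-up
horizon; event times live on the trial calendar (arrival + time) so pooled
event counts can trigger looks. The secular-trend multiplier (per unit
calendar time, default 1 = off) exists to make baseline drift expressible —
it is what the concurrent-control machinery protects against.

The intermediate outcome — an information-rich early endpoint on the causal
pathway, used for interim lack-of-benefit decisions — is modelled as a binary
outcome whose linear predictor is the definitive one scaled by a concordance
parameter `ρ ∈ [0,1]`: `ρ = 1` reproduces the definitive effects on the
intermediate scale, `ρ = 0` makes it treatment-independent. This single-knob
construction is a deliberate modelling choice: it spans "perfect interim
signal" to "useless interim signal" with one interpretable parameter.

Arrivals are deterministic at spacing 1/rate by default (a Poisson-process
option exists); per-intervention eligibility and per-randomisation consent
are independent Bernoulli draws.

What the generator does **not** emulate: informative censoring,
non-exponential hazards, covariate-dependent effects, continuous outcomes,
or operational gaps while a new arm is prepared. Passing tests therefore
establish the design arithmetic and the statistical operating properties
under these idealised conditions, not robustness to real-world violations.

## Monitoring

Look timing is driven by calendar time or by the τ-th outcome event **pooled
across all arms**. Per-comparison control-arm event counts are deliberately
unusable for scheduling: in a factorial design each comparison has a
different control group, and revealing the per-control split (e.g. 70 events
in the A-controls vs 50 in the B-controls) already hints at which arms are
performing better. `control_event_audit` computes those counts for Data
Monitoring Committee reports only, and the scheduler's interface accepts only
the pooled event stream.

Efficacy boundaries on the definitive outcome:

- **Haybittle-Peto** — fixed extreme interim threshold (default two-sided
  p* = 0.001, z ≈ 3.29) with the near-nominal fixed-sample quantile at the
  final look.
- **O'Brien-Fleming** — `c·sqrt(K/k)` with `c` solved numerically so the total
  null crossing probability equals α under equal information spacing.
- **Alpha-spending** — Lan-DeMets O'Brien-Fleming-like or Pocock-like spending
  functions; boundaries solved look by look.

All three use the same numerical core: the classic recursion for the
sub-density of the sequential z statistics restricted to the continuation
region, integrated by Simpson's rule on a grid spanning exactly the
continuation region at each look (801 points; boundary values accurate to
well under 1e-3). Unequal look spacing goes through the spending-function
path; the closed-form O'Brien-Fleming shape assumes equal spacing and warns
otherwise.

Futility (lack-of-benefit) rules are one-sided z thresholds per interim look
applied to the intermediate outcome, supplied in the monitoring plan; z is
signed so benefit is positive, and no futility stop is taken at the final
look. The z scale (rather than an effect-estimate scale) and the look spacing
are configuration choices, not inferences.

After an efficacy stop of a 2-way randomisation, the simulator by default
adopts the winner as scheme-fixed delivery for subsequent patients
(`adopt_winner`), which lowers the event rate for the remaining comparisons —
the dilution the planning module quantifies. An efficacy stop in a ≥3-way
randomisation removes only that arm; redesigning the surviving comparisons
around a newly proven arm (non-inferiority to the winner, combinations,
re-powering) is out of scope, as is any pause of the randomisation while such
a comparison is prepared.

## Analysis

`select_concurrent` implements the inclusion rule: randomised in the
comparison's randomisation, to one of its two arms, during a stage in which
both arms were open, with an eligible subset covering both arms. Scheme-fixed
and eligibility-driven deliveries are excluded (they were not randomised);
patients randomised to a third arm are excluded; every exclusion is logged
with its reason. "Concurrent" is operationalised as *same stage* — stages
exist precisely to mark scheme changes, and finer calendar matching within a
stage buys little once the stage term is in the model.

The primary per-comparison analysis is stage-stratified: Mantel-Haenszel
common odds ratio with the Robins-Breslow-Greenland standard error and the
Cochran-Mantel-Haenszel test for binary outcomes (implemented in closed form;
cross-checked in the tests against `statsmodels`' `StratifiedTable`), or a
stage-stratified Cox model (lifelines) for time-to-event. Strata with an
empty arm or with no (or all) events carry no information about the odds
ratio; they are dropped and logged, and an all-degenerate analysis returns an
explicit no-information result. No continuity corrections enter the MH sums
(the estimator handles zero cells natively); the 0.5 correction appears only
in the separate naive diagnostic estimator's single pooled table when a cell
is empty.

The combined model puts all interventions in one regression — logistic or
Cox — with one dummy per research intervention coding *receipt* (through
randomisation or scheme-fixed delivery) plus a categorical stage term. It is
main-effects only; stage-by-treatment terms are not included, keeping the
model aligned with the single-effect-per-intervention estimand. Degenerate
fits (separation) are flagged per coefficient rather than raised.

Interaction analyses split a comparison's concurrent set by the received
level of another randomisation and test homogeneity of the stage-stratified
log odds ratios with the inverse-variance Q statistic (χ², df = informative
subgroups − 1). Arms added late make their subgroup smaller — the tests
assert "strictly smaller" rather than an exact ratio, since the exact
fraction depends on when the arm joined.

The primary analysis stratifies by stage only; baseline stratification
factors can be added through configuration but are not part of the default
estimator.

## Planning arithmetic

`marginal_event_rate` mixes per-cell risks over the independent co-
intervention allocation cells; on the risk-ratio scale the mixture is exact
and linear in the baseline (`p0 Π_j (1 − f_j + f_j r_j)` for independent
co-interventions), and odds-ratio inputs are mapped through the logistic form
per cell before mixing. Sample size uses the standard pooled-variance
two-proportion normal approximation on the diluted rates (Bonferroni option
divides α by the number of comparisons); time-to-event targets use the
Schoenfeld events formula with the same dilution applied to the pooled event
probability and a constant-accrual duration back-out. `power_loss_curve`
evaluates the analytic power across a grid of co-intervention effects; it is
non-increasing as co-interventions become more effective, and the tests
verify it against Monte-Carlo simulation through the outcome model.

## Monte-Carlo machinery and reference study sizes

Each trial replicate consumes one seed, split into named substreams
(arrivals, randomisation, outcomes) via `numpy` SeedSequence spawning, so
extending one component never perturbs another's draws; replicate i of a
Monte-Carlo run uses `base_seed + i`. Identical seed and configuration give
byte-identical outputs.

The reference study conditions used by the test suite: type-I error and
familywise error on a 2×2 with 400 patients per comparison and control risk
0.3 (2000 replicates); concurrent-control bias on a single randomisation with
A2 added after 300 of ~1050 patients, control risk 0.15 and a 1.12× per-month
baseline trend (2000 replicates); combined-model coverage on a 2×2 with 400
patients per comparison, control risk 0.35 and a true A1 odds ratio of 0.5
(500 replicates); power dilution at 535 patients per arm with 4000
replicates per grid point. These sizes are large enough for the normal
approximations the analyses rely on while keeping full-suite replication
cheap.

## Known limitations

- Targets are patient counts in the planner; event-driven *timing* is
  supported for looks, but event-based completion targets are not planned
  deterministically.
- Interim looks fire only during recruitment; outcomes maturing after
  recruitment ends are analysed at the final analysis.
- Familywise error control is Bonferroni-or-nothing; Dunnett-type
  correlation-exact multi-arm boundaries are out of scope.
- Simultaneous (single cross-product) randomisation and minimisation are not
  implemented; the sequential scheme is the package's model.
- The odds ratio is non-collapsible: the combined model's conditional
  estimates and the marginal MH estimates agree only approximately when
  several interventions are simultaneously effective.
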