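"""Concurrent-control analysis of factorial-MAMS trial data.

The guiding principle: compare patients randomised to a research intervention
with their *concurrent* controls — patients randomised to the comparison's
control arm during stages in which both arms were open — and control for
trial stage in the analysis, because the mix of co-interventions and the
underlying risk can change between stages.  Patients allocated to either arm
other than through randomisation (scheme-fixed delivery, eligibility-driven
delivery) are excluded, as are patients whose eligible arm subset did not
cover both arms of the comparison.

The primary per-comparison analysis is stage-stratified: a Mantel-Haenszel
common odds ratio with the Cochran-Mantel-Haenszel test for binary outcomes
(Robins-Breslow-Greenland standard error for the log odds ratio), or a
stage-stratified Cox proportional-hazards model for time-to-event outcomes.
All z statistics are signed so that benefit (fewer/later events on research)
is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import TrialData
from .design import DesignError, TrialDesign

__all__ = [
    "AnalysisSet",
    "ComparisonResult",
    "select_concurrent",
    "stage_stratified_test",
    "naive_all_controls",
    "combined_model",
    "interaction_analysis",
]


@dataclass
class AnalysisSet:
    comparison: str
    randomisation_id: str
    research_arm: str
    control_arm: str
    indices: np.ndarray  # row indices into the TrialData
    stages: np.ndarray  # per-included-patient stage index
    exclusions: list[tuple[int, str]] = field(default_factory=list)  # (patient_id, reason)

    @property
    def n(self) -> int:
        return len(self.indices)


@dataclass
class ComparisonResult:
    comparison: str
    estimate: float  # log odds ratio / log hazard ratio (research vs control)
    se: float
    ci: tuple[float, float]
    z: float  # benefit-positive
    n_per_arm: dict
    events_per_arm: dict
    stage_table: list[dict]
    dropped_strata: list[int] = field(default_factory=list)
    no_information: bool = False
    method: str = "mantel-haenszel"

    def to_report(self) -> dict:
        return {
            "comparison": self.comparison,
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci),
            "z": self.z,
            "n_per_arm": self.n_per_arm,
            "events_per_arm": self.events_per_arm,
            "stages": self.stage_table,
            "dropped_strata": self.dropped_strata,
            "method": self.method,
        }


def _locate_comparison(design: TrialDesign, comparison: str):
    try:
        research, control = comparison.split("-vs-")
    except ValueError as exc:
        raise DesignError(f"unknown comparison {comparison!r}") from exc
    for stage in design.stages:
        for r in stage.scheme:
            ids = {a.id for a in r.arms}
            if research in ids and control in ids:
                return r.id, research, control
    raise DesignError(f"comparison {comparison!r} not found in any stage")


def _concurrent_stages(design: TrialDesign, rand_id: str, research: str, control: str) -> set[int]:
    out = set()
    for stage in design.stages:
        for r in stage.scheme:
            if r.id == rand_id and r.status == "open":
                ids = {a.id for a in r.arms}
                if research in ids and control in ids:
                    out.add(stage.index)
    return out


def select_concurrent(data: TrialData, comparison: str) -> AnalysisSet:
    """Concurrent-control analysis set for one pairwise comparison.

    A patient is included iff they were *randomised* in the comparison's
    randomisation to one of its two arms, during a stage in which both arms
    were open, and their eligible subset contained both arms.
    """
    rand_id, research, control = _locate_comparison(data.design, comparison)
    conc = _concurrent_stages(data.design, rand_id, research, control)
    assign = data.assignment[rand_id]
    mech = data.mechanism[rand_id]
    subsets = data.eligible_subset.get(rand_id)
    include = np.zeros(data.n, dtype=bool)
    exclusions: list[tuple[int, str]] = []
    for i in range(data.n):
        if mech[i] != "randomised":
            exclusions.append((int(data.patient_id[i]), "non-randomised allocation"))
            continue
        if assign[i] not in (research, control):
            exclusions.append((int(data.patient_id[i]), "randomised to another arm"))
            continue
        if int(data.stage[i]) not in conc:
            exclusions.append((int(data.patient_id[i]), "non-concurrent stage"))
            continue
        subset = subsets[i] if subsets is not None else None
        if subset is not None and not {research, control} <= subset:
            exclusions.append((int(data.patient_id[i]), "ineligible for one arm"))
            continue
        include[i] = True
    idx = np.nonzero(include)[0]
    return AnalysisSet(
        comparison=comparison,
        randomisation_id=rand_id,
        research_arm=research,
        control_arm=control,
        indices=idx,
        stages=data.stage[idx].astype(int),
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# Stage-stratified tests


def _mh_tables(treat, event, strata):
    """2x2 cell arrays (a, b, c, d) per stratum; a/b research, c/d control."""
    out = []
    for s in np.unique(strata):
        m = strata == s
        t, e = treat[m], event[m]
        a = int(np.sum(e[t]))
        b = int(np.sum(t) - a)
        c = int(np.sum(e[~t]))
        d = int(np.sum(~t) - c)
        out.append((int(s), a, b, c, d))
    return out


def _mantel_haenszel(tables):
    """MH common OR, RBG SE of the log OR, and the CMH z (benefit-positive)."""
    R = S = 0.0
    sum_a = sum_E = sum_V = 0.0
    prs = pss = qrs = qss = 0.0
    for _, a, b, c, d in tables:
        n = a + b + c + d
        if n == 0:
            continue
        R += a * d / n
        S += b * c / n
        n1, n0, m1, m0 = a + b, c + d, a + c, b + d
        sum_a += a
        sum_E += n1 * m1 / n
        if n > 1:
            sum_V += n1 * n0 * m1 * m0 / (n * n * (n - 1))
        p = (a + d) / n
        q = (b + c) / n
        r = a * d / n
        s = b * c / n
        prs += p * r
        pss += p * s
        qrs += q * r
        qss += q * s
    if R == 0 or S == 0 or sum_V == 0:
        return math.nan, math.nan, math.nan
    log_or = math.log(R / S)
    var = prs / (2 * R * R) + (pss + qrs) / (2 * R * S) + qss / (2 * S * S)
    z_benefit = (sum_E - sum_a) / math.sqrt(sum_V)
    return log_or, math.sqrt(var), z_benefit


def _informative(table) -> bool:
    _, a, b, c, d = table
    if a + b == 0 or c + d == 0:  # an empty arm
        return False
    if a + c == 0 or b + d == 0:  # no events, or all events
        return False
    return True


def stage_stratified_test(data: TrialData, analysis_set: AnalysisSet) -> ComparisonResult:
    """Stage-stratified estimate and test for one comparison.

    Binary outcomes: Mantel-Haenszel common odds ratio over stage strata with
    the Cochran-Mantel-Haenszel test.  Time-to-event: Cox proportional
    hazards stratified by stage (partial-likelihood z).  Strata carrying no
    information (an empty arm, or no/all events) are dropped and logged; if
    nothing informative remains an explicit no-information result is returned.
    """
    idx = analysis_set.indices
    treat = data.assignment[analysis_set.randomisation_id][idx] == analysis_set.research_arm
    strata = data.stage[idx].astype(int)
    n_per_arm = {
        analysis_set.research_arm: int(np.sum(treat)),
        analysis_set.control_arm: int(np.sum(~treat)),
    }
    if data.outcome_type == "binary":
        event = data.event[idx].astype(bool)
        tables = _mh_tables(treat, event, strata)
        kept = [t for t in tables if _informative(t)]
        dropped = [t[0] for t in tables if not _informative(t)]
        stage_table = [
            {"stage": s, "research": [a, b], "control": [c, d]} for s, a, b, c, d in tables
        ]
        events_per_arm = {
            analysis_set.research_arm: int(np.sum(event[treat])),
            analysis_set.control_arm: int(np.sum(event[~treat])),
        }
        if not kept:
            return ComparisonResult(
                analysis_set.comparison, math.nan, math.nan, (math.nan, math.nan),
                math.nan, n_per_arm, events_per_arm, stage_table, dropped,
                no_information=True,
            )
        log_or, se, z = _mantel_haenszel(kept)
        ci = (log_or - 1.959964 * se, log_or + 1.959964 * se)
        return ComparisonResult(
            analysis_set.comparison, log_or, se, ci, z, n_per_arm, events_per_arm,
            stage_table, dropped,
        )
    return _stratified_cox(data, analysis_set, treat, strata, n_per_arm)


def _stratified_cox(data, analysis_set, treat, strata, n_per_arm) -> ComparisonResult:
    import pandas as pd
    from lifelines import CoxPHFitter

    idx = analysis_set.indices
    dur = data.time_to_event[idx].astype(float)
    ev = data.event[idx].astype(int)
    events_per_arm = {
        analysis_set.research_arm: int(np.sum(ev[treat])),
        analysis_set.control_arm: int(np.sum(ev[~treat])),
    }
    stage_table = [
        {"stage": int(s), "events": int(np.sum(ev[strata == s])), "n": int(np.sum(strata == s))}
        for s in np.unique(strata)
    ]
    if ev.sum() == 0 or treat.all() or (~treat).all():
        return ComparisonResult(
            analysis_set.comparison, math.nan, math.nan, (math.nan, math.nan), math.nan,
            n_per_arm, events_per_arm, stage_table, [], no_information=True,
            method="stratified-cox",
        )
    df = pd.DataFrame({"duration": dur, "event": ev, "treat": treat.astype(int), "stage": strata})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event", strata="stage")
    coef = float(cph.params_["treat"])
    se = float(cph.standard_errors_["treat"])
    return ComparisonResult(
        analysis_set.comparison, coef, se,
        (coef - 1.959964 * se, coef + 1.959964 * se),
        -coef / se,  # benefit-positive: HR < 1 is benefit
        n_per_arm, events_per_arm, stage_table, [], method="stratified-cox",
    )


def naive_all_controls(data: TrialData, comparison: str) -> ComparisonResult:
    """Unstratified estimator ignoring concurrency (diagnostic only).

    Pools every patient ever randomised to either arm, across all stages,
    in a single 2x2 table — the estimator the concurrent-control principle
    exists to rule out.  Used to demonstrate bias under baseline drift.
    """
    rand_id, research, control = _locate_comparison(data.design, comparison)
    assign = data.assignment[rand_id]
    mech = data.mechanism[rand_id]
    m = (mech == "randomised") & ((assign == research) | (assign == control))
    treat = assign[m] == research
    event = data.event[m].astype(bool)
    a = float(np.sum(event[treat]))
    b = float(np.sum(treat) - a)
    c = float(np.sum(event[~treat]))
    d = float(np.sum(~treat) - c)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ComparisonResult(
        comparison, log_or, se, (log_or - 1.959964 * se, log_or + 1.959964 * se),
        -log_or / se,
        {research: int(np.sum(treat)), control: int(np.sum(~treat))},
        {research: int(np.sum(event[treat])), control: int(np.sum(event[~treat]))},
        [], method="naive-unstratified",
    )


# ---------------------------------------------------------------------------
# Combined model and interactions


def combined_model(data: TrialData) -> dict:
    """One regression over all patients with a dummy per research intervention.

    Binary outcomes: logistic regression; time-to-event: Cox model with stage
    strata.  Dummies code *receipt* of each research intervention (through
    randomisation or scheme-fixed delivery), and a categorical stage term
    preserves concurrency.  Returns per-intervention estimates; coefficients
    from degenerate fits (separation) are flagged.
    """
    research_arms = []
    for stage in data.design.stages:
        for r in sorted(stage.scheme, key=lambda x: x.position):
            for a in r.research_arms:
                if a.id not in research_arms:
                    research_arms.append(a.id)
    X_cols = [data.received(a).astype(float) for a in research_arms]
    names = list(research_arms)
    stages = data.stage.astype(int)
    stage_levels = np.unique(stages)
    for s in stage_levels[1:]:
        X_cols.append((stages == s).astype(float))
        names.append(f"stage_{s}")
    X = np.column_stack([np.ones(data.n)] + X_cols)

    if data.outcome_type == "binary":
        import statsmodels.api as sm

        y = data.event.astype(float)
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        coefs = fit.params[1:]
        ses = fit.bse[1:]
    else:
        import pandas as pd
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {name: col for name, col in zip(names, X_cols) if not name.startswith("stage_")}
        )
        df["duration"] = data.time_to_event
        df["event"] = data.event
        df["stage"] = stages
        cph = CoxPHFitter()
        cph.fit(df, duration_col="duration", event_col="event", strata="stage")
        coefs = np.array([cph.params_.get(a, math.nan) for a in research_arms])
        ses = np.array([cph.standard_errors_.get(a, math.nan) for a in research_arms])

    out = {}
    for j, arm in enumerate(research_arms):
        coef, se = float(coefs[j]), float(ses[j])
        flagged = not math.isfinite(coef) or not math.isfinite(se) or se > 50 or abs(coef) > 15
        out[arm] = {
            "estimate": coef,
            "se": se,
            "ci": (coef - 1.959964 * se, coef + 1.959964 * se),
            "z": -coef / se if se > 0 else math.nan,
            "flagged": flagged,
        }
    return out


def interaction_analysis(data: TrialData, comparison: str, by_randomisation: str) -> dict:
    """Subgroup effects by another randomisation's levels + homogeneity test.

    The comparison's concurrent analysis set is split by the *received* level
    of ``by_randomisation``; within each subgroup the stage-stratified
    estimate is computed, and homogeneity across subgroups is tested with the
    inverse-variance Q statistic (chi-square, df = informative subgroups - 1).
    """
    rand_id, _, _ = _locate_comparison(data.design, comparison)
    if by_randomisation == rand_id:
        raise DesignError("interaction requires a different randomisation than the comparison's")
    if by_randomisation not in data.randomisation_ids:
        raise DesignError(f"no randomisation {by_randomisation!r} in the dataset")
    aset = select_concurrent(data, comparison)
    levels = data.assignment[by_randomisation]
    subgroups: dict[str, ComparisonResult | None] = {}
    estimates, weights = [], []
    level_values = sorted({levels[i] for i in aset.indices if levels[i] is not None})
    if len(level_values) < 2:
        raise DesignError("fewer than two overlapping subgroup levels; no interaction to test")
    for lv in level_values:
        sub_idx = np.array([i for i in aset.indices if levels[i] == lv], dtype=int)
        if len(sub_idx) == 0:
            subgroups[lv] = None
            continue
        sub = AnalysisSet(
            aset.comparison, aset.randomisation_id, aset.research_arm, aset.control_arm,
            sub_idx, data.stage[sub_idx].astype(int),
        )
        res = stage_stratified_test(data, sub)
        subgroups[lv] = res
        if not res.no_information and math.isfinite(res.estimate):
            estimates.append(res.estimate)
            weights.append(1.0 / res.se**2)
    if len(estimates) < 2:
        return {"subgroups": subgroups, "Q": math.nan, "df": 0, "p_value": math.nan}
    est = np.asarray(estimates)
    w = np.asarray(weights)
    pooled = float(np.sum(w * est) / np.sum(w))
    Q = float(np.sum(w * (est - pooled) ** 2))
    df = len(est) - 1
    return {
        "subgroups": subgroups,
        "Q": Q,
        "df": df,
        "p_value": float(stats.chi2.sf(Q, df)),
        "pooled_estimate": pooled,
    }
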