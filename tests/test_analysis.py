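"""Concurrent-control selection, stratified tests, combined model, interactions."""

import math

import numpy as np
import pytest

from fmams import (
    DesignError,
    OutcomeModel,
    apply_adaptation,
    combined_model,
    interaction_analysis,
    make_factorial_design,
    select_concurrent,
    stage_stratified_test,
)
from fmams.analysis import naive_all_controls
from fmams.design import Adaptation
from fmams.outcomes import event_probability

from conftest import make_trial_data


def three_way_then_stop_design():
    design = make_factorial_design(
        [
            {
                "id": "A",
                "arms": [
                    {"id": "A0", "role": "control"},
                    {"id": "A1", "role": "research"},
                    {"id": "A2", "role": "research"},
                ],
            }
        ],
        1000,
    )
    return apply_adaptation(design, Adaptation("stop_lack_of_benefit", "A1"))


def test_patients_randomised_after_a_stop_are_not_concurrent_controls():
    design = three_way_then_stop_design()
    data = make_trial_data(
        design,
        stage=[1, 1, 2, 2],
        assignment={"A": ["A1", "A0", "A0", "A2"]},
        event=[0, 1, 0, 1],
    )
    aset = select_concurrent(data, "A1-vs-A0")
    assert list(data.patient_id[aset.indices]) == [1, 2]
    reasons = dict(aset.exclusions)
    assert reasons[3] == "non-concurrent stage"
    assert reasons[4] == "randomised to another arm"


def test_non_randomised_allocations_are_excluded_but_other_comparisons_keep_patient(design_2x2):
    # a patient contraindicated for A1 receives A0 without randomisation and
    # still enters randomisation B
    data = make_trial_data(
        design_2x2,
        stage=[1, 1, 1, 1],
        assignment={"A": ["A0", "A1", "A0", "A1"], "B": ["B1", "B0", "B0", "B1"]},
        mechanism={
            "A": ["not-eligible", "randomised", "randomised", "randomised"],
            "B": ["randomised"] * 4,
        },
        event=[0, 0, 1, 1],
    )
    aset_a = select_concurrent(data, "A1-vs-A0")
    assert 1 not in data.patient_id[aset_a.indices]
    assert dict(aset_a.exclusions)[1] == "non-randomised allocation"
    aset_b = select_concurrent(data, "B1-vs-B0")
    assert aset_b.n == 4


def test_reduced_eligibility_restricts_comparisons():
    design = make_factorial_design(
        [
            {
                "id": "A",
                "arms": [
                    {"id": "A0", "role": "control"},
                    {"id": "A1", "role": "research"},
                    {"id": "A2", "role": "research"},
                ],
            }
        ],
        1000,
    )
    data = make_trial_data(
        design,
        stage=[1, 1, 1],
        assignment={"A": ["A0", "A1", "A2"]},
        event=[0, 1, 0],
        eligible_subset={"A": [frozenset({"A0", "A2"}), None, None]},
    )
    a1 = select_concurrent(data, "A1-vs-A0")
    assert 1 not in data.patient_id[a1.indices]
    assert dict(a1.exclusions)[1] == "ineligible for one arm"
    a2 = select_concurrent(data, "A2-vs-A0")
    assert 1 in data.patient_id[a2.indices]


def test_full_eligibility_no_adaptation_includes_everyone(design_2x2):
    rng = np.random.default_rng(0)
    n = 60
    data = make_trial_data(
        design_2x2,
        stage=[1] * n,
        assignment={
            "A": rng.choice(["A0", "A1"], n),
            "B": rng.choice(["B0", "B1"], n),
        },
        event=rng.integers(0, 2, n),
    )
    assert select_concurrent(data, "A1-vs-A0").n == n


# ---------------------------------------------------------------------------
# Stage-stratified Mantel-Haenszel


def two_stage_design(design_2x2):
    return apply_adaptation(
        design_2x2, Adaptation("add_randomisation", "C", arms=(("C0", "control", 1), ("C1", "research", 1)))
    )


def data_from_tables(design, tables):
    """Build patient rows realising exact per-stage 2x2 tables."""
    stage, assign, event = [], [], []
    for s, (a, b, c, d) in tables:
        stage += [s] * (a + b + c + d)
        assign += ["A1"] * (a + b) + ["A0"] * (c + d)
        event += [1] * a + [0] * b + [1] * c + [0] * d
    return make_trial_data(design, stage=stage, assignment={"A": assign}, event=event)


def test_mantel_haenszel_matches_hand_computed_oracle(design_2x2):
    design = two_stage_design(design_2x2)
    tables = [(1, (10, 90, 20, 80)), (2, (5, 45, 10, 40))]
    data = data_from_tables(design, tables)
    res = stage_stratified_test(data, select_concurrent(data, "A1-vs-A0"))
    # closed-form MH: sum(a*d/n)/sum(b*c/n) = (4 + 2)/(9 + 4.5)
    assert math.exp(res.estimate) == pytest.approx(6 / 13.5, abs=1e-12)
    # independent cross-check: statsmodels StratifiedTable (MH + RBG SE + CMH)
    from statsmodels.stats.contingency_tables import StratifiedTable

    st = StratifiedTable(
        [np.array([[a, b], [c, d]]) for _, (a, b, c, d) in tables]
    )
    assert res.estimate == pytest.approx(st.logodds_pooled, abs=1e-10)
    assert res.se == pytest.approx(st.logodds_pooled_se, abs=1e-10)
    chi2 = st.test_null_odds(correction=False).statistic
    assert res.z**2 == pytest.approx(chi2, abs=1e-8)
    assert res.z > 0  # fewer research-arm events: benefit positive


def test_perfect_symmetry_gives_null_result(design_2x2):
    data = data_from_tables(design_2x2, [(1, (20, 80, 20, 80))])
    res = stage_stratified_test(data, select_concurrent(data, "A1-vs-A0"))
    assert res.estimate == pytest.approx(0.0)
    assert res.z == pytest.approx(0.0)


def test_uninformative_stratum_is_dropped(design_2x2):
    design = two_stage_design(design_2x2)
    with_empty = data_from_tables(design, [(1, (10, 90, 20, 80)), (2, (0, 50, 0, 50))])
    without = data_from_tables(design_2x2, [(1, (10, 90, 20, 80))])
    r1 = stage_stratified_test(with_empty, select_concurrent(with_empty, "A1-vs-A0"))
    r2 = stage_stratified_test(without, select_concurrent(without, "A1-vs-A0"))
    assert r1.dropped_strata == [2]
    assert r1.estimate == pytest.approx(r2.estimate)
    assert r1.z == pytest.approx(r2.z)


def test_all_strata_degenerate_yields_no_information(design_2x2):
    data = data_from_tables(design_2x2, [(1, (0, 50, 0, 50))])
    res = stage_stratified_test(data, select_concurrent(data, "A1-vs-A0"))
    assert res.no_information


def test_stratified_cox_recovers_hazard_ratio(design_2x2):
    rng = np.random.default_rng(3)
    n = 4000
    arm = rng.integers(0, 2, n)
    lam = np.where(arm == 1, 0.5 * 0.4, 0.4)
    t = rng.exponential(1 / lam)
    event = (t <= 5.0).astype(int)
    obs = np.minimum(t, 5.0)
    data = make_trial_data(
        design_2x2,
        stage=[1] * n,
        assignment={"A": np.where(arm == 1, "A1", "A0")},
        event=event,
        outcome_type="tte",
        time_to_event=obs,
    )
    res = stage_stratified_test(data, select_concurrent(data, "A1-vs-A0"))
    assert res.method == "stratified-cox"
    assert res.estimate == pytest.approx(math.log(0.5), abs=0.1)
    assert res.z > 3  # strong benefit


# ---------------------------------------------------------------------------
# Combined model


def simulate_factorial(design, rng, n, model, stage=None):
    a = rng.choice(["A0", "A1"], n)
    b = rng.choice(["B0", "B1"], n)
    p = np.array([event_probability([ai, bi], model) for ai, bi in zip(a, b)])
    y = (rng.random(n) < p).astype(int)
    return make_trial_data(
        design, stage=stage if stage is not None else [1] * n,
        assignment={"A": a, "B": b}, event=y,
    )


def test_combined_model_null_recovery(design_2x2):
    rng = np.random.default_rng(8)
    model = OutcomeModel(outcome_type="binary", baseline=0.3)
    data = simulate_factorial(design_2x2, rng, 20_000, model)
    fit = combined_model(data)
    for arm in ("A1", "B1"):
        assert abs(fit[arm]["estimate"]) < 3.5 * fit[arm]["se"]
        assert not fit[arm]["flagged"]


def test_combined_model_recovers_generated_effect(design_2x2):
    rng = np.random.default_rng(9)
    model = OutcomeModel(outcome_type="binary", baseline=0.35, effects={"A1": 0.5})
    data = simulate_factorial(design_2x2, rng, 20_000, model)
    fit = combined_model(data)
    lo, hi = fit["A1"]["ci"]
    assert lo <= math.log(0.5) <= hi
    assert abs(fit["B1"]["estimate"]) < 3.5 * fit["B1"]["se"]


def test_combined_model_single_stage_equals_unstratified_fit(design_2x2):
    import statsmodels.api as sm

    rng = np.random.default_rng(10)
    model = OutcomeModel(outcome_type="binary", baseline=0.3, effects={"A1": 0.7})
    data = simulate_factorial(design_2x2, rng, 5_000, model)
    fit = combined_model(data)
    X = np.column_stack(
        [np.ones(data.n), data.received("A1").astype(float), data.received("B1").astype(float)]
    )
    ref = sm.GLM(data.event.astype(float), X, family=sm.families.Binomial()).fit()
    assert fit["A1"]["estimate"] == pytest.approx(ref.params[1], abs=1e-8)


def test_combined_model_agrees_with_per_comparison_tests(design_2x2):
    rng = np.random.default_rng(11)
    model = OutcomeModel(outcome_type="binary", baseline=0.3, effects={"A1": 0.6, "B1": 0.85})
    data = simulate_factorial(design_2x2, rng, 8_000, model)
    fit = combined_model(data)
    for cid, arm in (("A1-vs-A0", "A1"), ("B1-vs-B0", "B1")):
        mh = stage_stratified_test(data, select_concurrent(data, cid))
        assert np.sign(mh.estimate) == np.sign(fit[arm]["estimate"])
        assert abs(mh.estimate - fit[arm]["estimate"]) < 0.1


# ---------------------------------------------------------------------------
# Interactions


def test_interaction_homogeneity_null_rejection_rate(design_2x2):
    rng = np.random.default_rng(12)
    model = OutcomeModel(outcome_type="binary", baseline=0.3, effects={"A1": 0.7})
    reps, rej = 300, 0
    for _ in range(reps):
        data = simulate_factorial(design_2x2, rng, 800, model)
        out = interaction_analysis(data, "A1-vs-A0", "B")
        rej += out["p_value"] < 0.05
    rate = rej / reps
    se = math.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) <= 3 * se


def test_interaction_requires_another_randomisation():
    design = make_factorial_design(
        [{"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]}],
        100,
    )
    data = make_trial_data(design, stage=[1, 1], assignment={"A": ["A0", "A1"]}, event=[0, 1])
    with pytest.raises(DesignError):
        interaction_analysis(data, "A1-vs-A0", "A")
    with pytest.raises(DesignError):
        interaction_analysis(data, "A1-vs-A0", "Z")


def test_naive_estimator_uses_all_stages(design_2x2):
    design = two_stage_design(design_2x2)
    data = data_from_tables(design, [(1, (10, 90, 20, 80)), (2, (5, 45, 10, 40))])
    res = naive_all_controls(data, "A1-vs-A0")
    # single pooled 2x2: (15, 135, 30, 120)
    assert math.exp(res.estimate) == pytest.approx((15 * 120) / (135 * 30), abs=1e-12)


def test_factorial_estimate_variance_matches_two_arm_trial(design_2x2):
    """A 2x2 factorial answers the A question with a whole-trial-sized sample."""
    rng = np.random.default_rng(13)
    model = OutcomeModel(outcome_type="binary", baseline=0.3)
    n, reps = 1000, 300
    fact, two_arm = [], []
    for _ in range(reps):
        data = simulate_factorial(design_2x2, rng, n, model)
        fact.append(stage_stratified_test(data, select_concurrent(data, "A1-vs-A0")).estimate)
        arm = rng.integers(0, 2, n)
        y = rng.random(n) < 0.3
        a, b = y[arm == 1].sum() + 0.5, (arm == 1).sum() - y[arm == 1].sum() + 0.5
        c, d = y[arm == 0].sum() + 0.5, (arm == 0).sum() - y[arm == 0].sum() + 0.5
        two_arm.append(math.log(a * d / (b * c)))
    ratio = np.var(fact, ddof=1) / np.var(two_arm, ddof=1)
    assert 0.75 < ratio < 1.35
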