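import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fmams import TrialData, make_factorial_design
from fmams.design import Adaptation

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SPECS_2X2 = [
    {"id": "A", "arms": [{"id": "A0", "role": "control"}, {"id": "A1", "role": "research"}]},
    {"id": "B", "arms": [{"id": "B0", "role": "control"}, {"id": "B1", "role": "research"}]},
]


@pytest.fixture
def specs_2x2():
    return [dict(s, arms=[dict(a) for a in s["arms"]]) for s in SPECS_2X2]


@pytest.fixture
def design_2x2(specs_2x2):
    """Unadapted 2x2 factorial, 3000 patients per comparison."""
    return make_factorial_design(specs_2x2, 3000)


@pytest.fixture
def design_table2(specs_2x2):
    """The illustrative adapted design: A2 joins randomisation A after 1500."""
    return make_factorial_design(
        specs_2x2,
        3000,
        accrual_rate=100,
        planned_adaptations=[Adaptation("add_intervention", "A", 1500, new_arm="A2")],
    )


def make_trial_data(
    design,
    stage,
    assignment,
    event,
    mechanism=None,
    eligible_subset=None,
    outcome_type="binary",
    intermediate=None,
    time_to_event=None,
):
    """Assemble a TrialData from plain arrays (test helper)."""
    stage = np.asarray(stage)
    n = len(stage)
    rand_ids = list(assignment)
    assignment = {r: np.asarray(v, dtype=object) for r, v in assignment.items()}
    if mechanism is None:
        mechanism = {
            r: np.where(np.equal(assignment[r], None), "not-eligible", "randomised")
            for r in rand_ids
        }
    else:
        mechanism = {r: np.asarray(v, dtype=object) for r, v in mechanism.items()}
    return TrialData(
        design=design,
        randomisation_ids=rand_ids,
        patient_id=np.arange(1, n + 1),
        arrival=np.arange(n, dtype=float),
        stage=stage,
        assignment=assignment,
        mechanism=mechanism,
        eligible_subset=eligible_subset or {r: None for r in rand_ids},
        outcome_type=outcome_type,
        event=np.asarray(event, dtype=np.int8),
        time_to_event=None if time_to_event is None else np.asarray(time_to_event, float),
        outcome_time=np.zeros(n),
        intermediate=None if intermediate is None else np.asarray(intermediate, dtype=np.int8),
    )
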