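import numpy as np
import pandas as pd
import pytest

from rplt.model import AgentParams, simulate_agent
from rplt.task import canonical_schedule


@pytest.fixture(scope="session")
def schedule():
    return canonical_schedule()


@pytest.fixture(scope="session")
def learner_session(schedule):
    """One simulated session from a moderately greedy learner."""
    return simulate_agent(
        schedule,
        AgentParams(0.5, 0.4, 0.25, 0.1),
        seed=42,
        session_id="fixture-learner",
        subject_id="fixture-subject",
    )


def make_trial_row(
    trial_index,
    stimulus_id,
    response,
    feedback,
    assigned_category="A",
    rt_ms=700.0,
    practice=False,
    session_id="hand",
    subject_id="hand-subject",
):
    """Hand-built trial-log row with the package's column schema."""
    from rplt.task import STIMULI

    valence = STIMULI[stimulus_id].valence if stimulus_id in STIMULI else "reward"
    return {
        "session_id": session_id,
        "subject_id": subject_id,
        "trial_index": trial_index,
        "block": 1 if trial_index <= 40 else 2,
        "practice_flag": practice,
        "stimulus_id": stimulus_id,
        "valence": valence,
        "assigned_category": assigned_category,
        "response": response,
        "correct": response == assigned_category,
        "feedback": feedback,
        "tally_after": 500,
        "rt_ms": rt_ms,
    }


@pytest.fixture
def trial_row_factory():
    return make_trial_row


def frame_from_rows(rows):
    return pd.DataFrame(rows)
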