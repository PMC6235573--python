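import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import peakshift as ps

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset() -> ps.Dataset:
    """A small but complete 16-to-32 simulation shared across tests."""
    return ps.simulate_design(
        "exp1_16to32", seed=7, n_subjects=3,
        sessions_train=2, trials_per_session_train=80,
        sessions_change=1, trials_per_session_change=20,
        sessions_test=2, trials_per_session_test=60,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_probe(responses, probe_duration=48.0, cue="short", duration=8.0,
               subject="s01", phase="train", session=1, index=1, context="A"):
    """Hand-built probe trial for unit tests."""
    return ps.TrialRecord(
        subject_id=subject, group="g", context=context, phase=phase,
        session=session, trial_index=index, cue_id=cue, trial_type="probe",
        programmed_duration=duration, probe_duration=probe_duration,
        reinforced_time=None, responses=np.asarray(responses, dtype=float),
    )


def make_fi(responses, reinforced_time, cue="short", duration=8.0,
            subject="s01", phase="train", session=1, index=1, context="A"):
    return ps.TrialRecord(
        subject_id=subject, group="g", context=context, phase=phase,
        session=session, trial_index=index, cue_id=cue, trial_type="fi",
        programmed_duration=duration, probe_duration=None,
        reinforced_time=reinforced_time,
        responses=np.asarray(responses, dtype=float),
    )
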