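"""Shared fixtures: montage, small schedules, and one simulated session.

The simulated-session fixture is module-scoped and deliberately small
(1 participant, 2 sequences, 1 session = 96 trials) so every preprocessing
and connectivity test can share it without re-simulating.
"""

import numpy as np
import pytest

from micnet.paradigm import SessionSpec, build_schedule, standard_montage
from micnet.preprocess import bandpass_notch, epoch, reject_artifacts
from micnet.synthgen import (
    DEFAULT_TONGUE_EDGES,
    ArtifactModel,
    LatentSourceModel,
    simulate_recording,
)

#: The 19 published significant channel-index pairs of the tongue contrast.
TABLE1_EDGES = DEFAULT_TONGUE_EDGES


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def study_spec():
    return SessionSpec()


@pytest.fixture(scope="session")
def short_spec():
    """One participant, one session, two sequences: 96 trials."""
    return SessionSpec(
        n_participants=1, sessions_per_participant=1, sequences_per_session=2
    )


@pytest.fixture(scope="session")
def short_schedule(short_spec):
    return build_schedule(short_spec, seed=101)


@pytest.fixture(scope="session")
def short_recording(short_schedule):
    return simulate_recording(
        short_schedule.subset(participant_id=1, session_index=1),
        model=LatentSourceModel(),
        artifacts=ArtifactModel(),
        seed=101,
    )


@pytest.fixture(scope="session")
def clean_recording(short_schedule):
    """Same session with artifact injection disabled."""
    return simulate_recording(
        short_schedule.subset(participant_id=1, session_index=1),
        model=LatentSourceModel(),
        artifacts=ArtifactModel(eog_trial_rate=0.0, emg_trial_rate=0.0),
        seed=101,
    )


@pytest.fixture(scope="session")
def clean_epochs(clean_recording):
    eps, _ = reject_artifacts(epoch(bandpass_notch(clean_recording)))
    return eps


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
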