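"""Experiment design: montage, trial timing, session structure, schedules.

The paradigm is a cue-based synchronous four-class motor-imagery (MI) task.
Each trial starts with a beep (t = 0) and an immediate 2 s fixation cross
(the baseline window), followed by a 1.25 s arrow cue (left arrow -> left
hand, right -> right hand, down -> feet, up -> tongue) and a 2 s imagery
window, then an inter-trial break of about 2 s.  A session holds six
sequences; within each sequence every task appears 12 times in randomized
order.  Each participant completes two sessions.

Channel identity throughout the package is the 1-based INDEX in the fixed
22-channel montage order; electrode names are labels attached to indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TASK_LABELS",
    "Montage",
    "SessionSpec",
    "TrialEvent",
    "TrialSchedule",
    "standard_montage",
    "build_schedule",
    "trial_counts",
    "classify_edge_hemisphere",
]

#: The four imagery task labels, in cue order (left, right, down, up arrows).
TASK_LABELS: tuple[str, ...] = ("left_hand", "right_hand", "feet", "tongue")

#: Recording order of the 22 scalp electrodes (10-20 system, left-mastoid
#: reference).  Channel index = 1-based position in this tuple.
_CHANNELS_1020: tuple[str, ...] = (
    "Fz", "FC1", "FC3", "FCz", "FC2", "FC4", "T7", "C3", "C1", "Cz", "C2",
    "C4", "T8", "CP3", "CP1", "CPz", "CP2", "CP4", "P3", "Pz", "P2", "Oz",
)


class InvalidSpecError(ValueError):
    """Raised when a session specification fails validation."""


def _hemisphere_from_name(name: str) -> str:
    # 10-20 convention: odd terminal digit -> left, even -> right, 'z' -> midline.
    last = name[-1]
    if last in ("z", "Z"):
        return "midline"
    digit = int(last)
    return "left" if digit % 2 == 1 else "right"


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with index/name/hemisphere lookups.

    Indices are 1-based positions in the recording order.
    """

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names in montage")

    def __len__(self) -> int:
        return len(self.channels)

    def index_of(self, name: str) -> int:
        """1-based channel index of an electrode name."""
        try:
            return self.channels.index(name) + 1
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def name_of(self, index: int) -> str:
        """Electrode name at a 1-based channel index."""
        if not 1 <= index <= len(self.channels):
            raise IndexError(f"channel index {index} outside 1..{len(self.channels)}")
        return self.channels[index - 1]

    def hemisphere_of(self, name: str) -> str:
        """'left', 'right' or 'midline' under the 10-20 suffix convention."""
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}")
        return _hemisphere_from_name(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, len(self.channels) + 1),
                "name": list(self.channels),
                "hemisphere": [_hemisphere_from_name(c) for c in self.channels],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def standard_montage() -> Montage:
    """The fixed 22-channel 10-20 montage in recording order."""
    return Montage(channels=_CHANNELS_1020)


@dataclass(frozen=True)
class SessionSpec:
    """Counts and timing of the cue paradigm.

    Defaults are the study design: 4 tasks x 12 repetitions x 6 sequences
    per session (288 trials/session), 2 sessions for each of 19
    participants, 250 Hz sampling, 2 s fixation baseline, 1.25 s cue, 2 s
    imagery and a 2 s inter-trial interval.
    """

    n_tasks: int = 4
    reps_per_task_per_sequence: int = 12
    sequences_per_session: int = 6
    sessions_per_participant: int = 2
    n_participants: int = 19
    fixation_s: float = 2.0
    cue_s: float = 1.25
    imagery_s: float = 2.0
    iti_s: float = 2.0
    sample_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        counts = {
            "n_tasks": self.n_tasks,
            "reps_per_task_per_sequence": self.reps_per_task_per_sequence,
            "sequences_per_session": self.sequences_per_session,
            "sessions_per_participant": self.sessions_per_participant,
            "n_participants": self.n_participants,
        }
        for key, value in counts.items():
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise InvalidSpecError(f"{key} must be an integer, got {value!r}")
            if value < 0:
                raise InvalidSpecError(f"{key} must be non-negative, got {value}")
        for key in ("fixation_s", "cue_s", "imagery_s", "iti_s", "sample_rate_hz"):
            value = getattr(self, key)
            if not value > 0:
                raise InvalidSpecError(f"{key} must be positive, got {value}")
        if self.n_tasks > len(TASK_LABELS):
            raise InvalidSpecError(
                f"n_tasks {self.n_tasks} exceeds the {len(TASK_LABELS)} defined labels"
            )

    @property
    def trial_span_s(self) -> float:
        """Full footprint of one trial: fixation + cue + imagery + ITI."""
        return self.fixation_s + self.cue_s + self.imagery_s + self.iti_s

    @property
    def task_labels(self) -> tuple[str, ...]:
        return TASK_LABELS[: self.n_tasks]

    def with_overrides(self, **kwargs) -> "SessionSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialEvent:
    """One cued trial.  onset_s is the beep time (t = 0 of the trial)."""

    onset_s: float
    task_label: str
    sequence_index: int
    session_index: int
    participant_id: int


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial events, possibly spanning sessions and participants."""

    events: tuple[TrialEvent, ...]
    spec: SessionSpec = field(default_factory=SessionSpec)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def participants(self) -> tuple[int, ...]:
        return tuple(sorted({e.participant_id for e in self.events}))

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted({e.session_index for e in self.events}))

    def subset(
        self, participant_id: int | None = None, session_index: int | None = None
    ) -> "TrialSchedule":
        kept = tuple(
            e
            for e in self.events
            if (participant_id is None or e.participant_id == participant_id)
            and (session_index is None or e.session_index == session_index)
        )
        return TrialSchedule(events=kept, spec=self.spec)

    def span_s(self) -> float:
        """Time from 0 to the end of the last trial's footprint (one session)."""
        if not self.events:
            return 0.0
        return max(e.onset_s for e in self.events) + self.spec.trial_span_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [round(e.onset_s, 3) for e in self.events],
                "duration": [
                    round(self.spec.fixation_s + self.spec.cue_s + self.spec.imagery_s, 3)
                ]
                * len(self.events),
                "trial_type": [e.task_label for e in self.events],
                "sequence": [e.sequence_index for e in self.events],
                "session": [e.session_index for e in self.events],
                "participant": [e.participant_id for e in self.events],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write a BIDS-events-compatible tab-separated table."""
        df = self.to_frame()
        df["onset"] = df["onset"].map(lambda x: f"{x:.3f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, spec: SessionSpec | None = None) -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t")
        events = tuple(
            TrialEvent(
                onset_s=float(row.onset),
                task_label=str(row.trial_type),
                sequence_index=int(row.sequence),
                session_index=int(row.session),
                participant_id=int(row.participant),
            )
            for row in df.itertuples()
        )
        return cls(events=events, spec=spec or SessionSpec())


def build_schedule(spec: SessionSpec, seed: int) -> TrialSchedule:
    """Randomized trial schedule for the full study population.

    Within every sequence each task label occurs exactly
    ``reps_per_task_per_sequence`` times, shuffled by a deterministic
    per-(participant, session, sequence) substream of ``seed``.  Onsets are
    relative to the start of each session and advance by the fixed trial
    footprint (fixation + cue + imagery + ITI).
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise InvalidSpecError(f"seed must be an integer, got {seed!r}")
    labels = np.array(spec.task_labels)
    base_block = np.repeat(
        np.arange(spec.n_tasks), spec.reps_per_task_per_sequence
    )
    events: list[TrialEvent] = []
    for participant in range(1, spec.n_participants + 1):
        for session in range(1, spec.sessions_per_participant + 1):
            onset = 0.0
            for sequence in range(1, spec.sequences_per_session + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=int(seed) & 0x7FFFFFFF,
                        spawn_key=(participant, session, sequence),
                    )
                )
                order = rng.permutation(base_block)
                for task_idx in order:
                    events.append(
                        TrialEvent(
                            onset_s=onset,
                            task_label=str(labels[task_idx]),
                            sequence_index=sequence,
                            session_index=session,
                            participant_id=participant,
                        )
                    )
                    onset += spec.trial_span_s
    return TrialSchedule(events=tuple(events), spec=spec)


def trial_counts(spec: SessionSpec) -> dict[str, int]:
    """Derived trial counts for a session specification.

    For the study design this gives 72 trials per task per session, 288 per
    session, 576 per participant and 10,944 in total.
    """
    per_task_per_session = spec.reps_per_task_per_sequence * spec.sequences_per_session
    per_session = per_task_per_session * spec.n_tasks
    per_participant = per_session * spec.sessions_per_participant
    total = per_participant * spec.n_participants
    return {
        "per_task_per_session": per_task_per_session,
        "per_session": per_session,
        "per_participant": per_participant,
        "total": total,
    }


class SelfLoopError(ValueError):
    """Raised for an electrode paired with itself."""


def classify_edge_hemisphere(
    edge: tuple[int, int], montage: Montage | None = None
) -> str:
    """Classify an electrode pair as 'left', 'right' or 'bilateral'.

    Strict rule: 'left' ('right') only when BOTH endpoints are left (right)
    hemisphere electrodes; any midline endpoint or cross-hemisphere pair is
    'bilateral'.  Endpoints are 1-based channel indices.
    """
    montage = montage or standard_montage()
    i, j = edge
    if i == j:
        raise SelfLoopError(f"self-loop edge ({i}, {j})")
    sides = {montage.hemisphere_of(montage.name_of(int(i))),
             montage.hemisphere_of(montage.name_of(int(j)))}
    if sides == {"left"}:
        return "left"
    if sides == {"right"}:
        return "right"
    return "bilateral"
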