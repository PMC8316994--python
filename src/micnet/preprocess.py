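"""Filtering, epoching, artifact rejection and QC bookkeeping.

The preprocessing chain mirrors the recording settings: zero-phase
band-pass 0.5-100 Hz (4th-order Butterworth, applied forward-backward)
followed by a 50 Hz notch (quality factor 30), then extraction of two
500-sample windows per trial at 250 Hz — the 2 s fixation baseline starting
at the trial onset (beep) and the 2 s imagery window starting at cue
offset.  Rejection is threshold-based: a trial is an EOG artifact when the
peak absolute EOG amplitude inside its windows exceeds a voltage threshold,
and an EMG artifact when its mean 30-100 Hz EEG band power exceeds a
multiple of the session-median trial band power.  A trial showing both is
counted once, under EOG, so the category percentages are additive.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from micnet.paradigm import TrialSchedule
from micnet.synthgen import N_EEG, N_EOG, Recording

__all__ = [
    "EpochSet",
    "QCReport",
    "RejectionThresholds",
    "bandpass_notch",
    "epoch",
    "reject_artifacts",
]

logger = logging.getLogger(__name__)

BASELINE_LABEL = "baseline"


@dataclass
class EpochSet:
    """Labeled fixed-length trial windows.

    ``epochs`` is trials x channels x samples (µV, EEG channels only);
    ``labels`` holds 'baseline' or a task label per epoch; ``eog`` carries
    the time-aligned EOG windows for artifact screening.
    """

    epochs: np.ndarray
    labels: np.ndarray
    participant_id: int
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    eog: np.ndarray | None = None
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.labels), dtype=bool)
        self.labels = np.asarray(self.labels, dtype=object)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("labels length must equal epoch count")
        if len(self.kept_mask) != len(self.labels):
            raise ValueError("kept_mask length must equal epoch count")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def select(self, label: str, kept_only: bool = True) -> np.ndarray:
        """Epoch tensor for one condition label."""
        mask = self.labels == label
        if kept_only:
            mask &= self.kept_mask
        return self.epochs[mask]

    def save(self, prefix: str | Path) -> None:
        """Kept-epoch tensor as flat float32 binary + JSON header."""
        prefix = Path(prefix)
        kept = self.epochs[self.kept_mask].astype("<f4")
        kept.tofile(prefix.with_suffix(".dat"))
        header = {
            "format": "micnet-epochs-v1",
            "dtype": "<f4",
            "shape": list(kept.shape),
            "units": "uV",
            "participant_id": int(self.participant_id),
            "labels": [str(l) for l in self.labels[self.kept_mask]],
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochSet":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        data = np.fromfile(prefix.with_suffix(".dat"), dtype=header["dtype"])
        data = data.reshape(header["shape"]).astype(float)
        return cls(
            epochs=data,
            labels=np.array(header["labels"], dtype=object),
            participant_id=header["participant_id"],
        )


@dataclass(frozen=True)
class QCReport:
    """Per-session trial-rejection summary, percentages to one decimal.

    ``pct_preserved`` is defined as 100 − pct_eog_rejected − pct_emg_rejected
    so the three categories are exactly additive.
    """

    n_trials: int
    pct_eog_rejected: float
    pct_emg_rejected: float

    @property
    def pct_preserved(self) -> float:
        return round(float(100.0 - self.pct_eog_rejected - self.pct_emg_rejected), 1)

    @classmethod
    def from_rates(cls, n_trials: int, eog_rate: float, emg_rate: float) -> "QCReport":
        """Build from fractional rejection rates (e.g. 0.048 and 0.012)."""
        return cls(
            n_trials=int(n_trials),
            pct_eog_rejected=round(float(100.0 * eog_rate), 1),
            pct_emg_rejected=round(float(100.0 * emg_rate), 1),
        )

    def to_dict(self) -> dict:
        return {
            "n_trials": int(self.n_trials),
            "pct_eog_rejected": float(self.pct_eog_rejected),
            "pct_emg_rejected": float(self.pct_emg_rejected),
            "pct_preserved": float(self.pct_preserved),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class RejectionThresholds:
    """EOG peak-amplitude and EMG relative band-power thresholds."""

    eog_threshold_uv: float = 100.0
    emg_multiplier: float = 3.0
    emg_band_hz: tuple[float, float] = (30.0, 100.0)

    def __post_init__(self) -> None:
        if self.eog_threshold_uv <= 0 or self.emg_multiplier <= 0:
            raise ValueError("rejection thresholds must be positive")


def _design_bandpass(fs: float, low: float, high: float):
    nyq = fs / 2
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist {nyq} Hz")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_notch(
    recording: Recording,
    low_hz: float = 0.5,
    high_hz: float = 100.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase 0.5-100 Hz band-pass then 50 Hz notch, all channels.

    Output has the same length and channel layout as the input.
    """
    fs = recording.sample_rate_hz
    sos = _design_bandpass(fs, low_hz, high_hz)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=0)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    filtered = signal.filtfilt(b, a, filtered, axis=0)
    return Recording(
        data=np.ascontiguousarray(filtered),
        sample_rate_hz=fs,
        schedule=recording.schedule,
        truth=recording.truth,
    )


def epoch(recording: Recording, schedule: TrialSchedule | None = None) -> EpochSet:
    """Cut baseline and imagery windows out of a continuous recording.

    Per trial: a half-open 500-sample baseline window starting at the
    fixation onset (= trial onset) and a 500-sample imagery window starting
    at cue offset.  Trials extending past the end of the recording are
    dropped with a warning.
    """
    schedule = schedule if schedule is not None else recording.schedule
    spec = schedule.spec
    fs = recording.sample_rate_hz
    win = int(round(spec.imagery_s * fs))
    base_win = int(round(spec.fixation_s * fs))
    if base_win != win:
        # Baseline and imagery windows are equal by design (2 s each); keep
        # the common length so the correlation estimates are comparable.
        win = min(win, base_win)
    n_samples = recording.data.shape[0]

    epochs: list[np.ndarray] = []
    eogs: list[np.ndarray] = []
    labels: list[str] = []
    trial_idx: list[int] = []
    participants = schedule.participants
    participant = participants[0] if participants else -1
    for t, event in enumerate(schedule):
        base_start = int(round(event.onset_s * fs))
        imag_start = int(round((event.onset_s + spec.fixation_s + spec.cue_s) * fs))
        if imag_start + win > n_samples or base_start + win > n_samples:
            warnings.warn(
                f"trial {t} at {event.onset_s:.3f}s extends past end of recording; dropped",
                stacklevel=2,
            )
            continue
        for start, label in ((base_start, BASELINE_LABEL), (imag_start, event.task_label)):
            epochs.append(recording.eeg[start : start + win].T)
            eogs.append(recording.eog[start : start + win].T)
            labels.append(label)
            trial_idx.append(t)
    if not epochs:
        return EpochSet(
            epochs=np.empty((0, N_EEG, win)),
            labels=np.array([], dtype=object),
            participant_id=participant,
            eog=np.empty((0, N_EOG, win)),
            trial_index=np.array([], dtype=int),
        )
    return EpochSet(
        epochs=np.stack(epochs),
        labels=np.array(labels, dtype=object),
        participant_id=participant,
        eog=np.stack(eogs),
        trial_index=np.array(trial_idx, dtype=int),
    )


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Mean power in a band per epoch, averaged over channels (Welch)."""
    freqs, psd = signal.welch(x, fs=fs, nperseg=min(256, x.shape[-1]), axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return psd[..., sel].mean(axis=(-2, -1))


def reject_artifacts(
    epochs: EpochSet,
    eog: np.ndarray | None = None,
    thresholds: RejectionThresholds | None = None,
    sample_rate_hz: float = 250.0,
) -> tuple[EpochSet, QCReport]:
    """Flag EOG/EMG-contaminated trials and update the kept mask.

    A trial (baseline + imagery windows combined) is rejected as EOG when
    max |EOG| in its windows exceeds ``eog_threshold_uv``; otherwise as EMG
    when its mean 30-100 Hz EEG band power exceeds ``emg_multiplier`` times
    the session median.  Percentages refer to trials, not epochs.
    """
    thresholds = thresholds or RejectionThresholds()
    eog = eog if eog is not None else epochs.eog
    if eog is None:
        raise ValueError("EOG traces required for artifact rejection")
    if eog.shape[0] != len(epochs):
        raise ValueError("EOG traces not aligned with epochs")
    if epochs.trial_index is None:
        trial_index = np.arange(len(epochs))
    else:
        trial_index = epochs.trial_index

    trials = np.unique(trial_index)
    n_trials = len(trials)
    if n_trials == 0:
        return epochs, QCReport(n_trials=0, pct_eog_rejected=0.0, pct_emg_rejected=0.0)

    eog_peak_per_epoch = np.abs(eog).max(axis=(1, 2))
    emg_power_per_epoch = _band_power(epochs.epochs, sample_rate_hz, thresholds.emg_band_hz)

    eog_trial = np.zeros(n_trials, dtype=bool)
    emg_trial = np.zeros(n_trials, dtype=bool)
    trial_power = np.zeros(n_trials)
    for k, t in enumerate(trials):
        sel = trial_index == t
        eog_trial[k] = eog_peak_per_epoch[sel].max() > thresholds.eog_threshold_uv
        trial_power[k] = emg_power_per_epoch[sel].mean()
    median_power = np.median(trial_power)
    emg_trial = trial_power > thresholds.emg_multiplier * median_power
    emg_trial &= ~eog_trial  # dual-artifact trials counted once, under EOG

    rejected_trials = {int(trials[k]) for k in np.flatnonzero(eog_trial | emg_trial)}
    kept_mask = np.array([int(t) not in rejected_trials for t in trial_index])
    out = EpochSet(
        epochs=epochs.epochs,
        labels=epochs.labels,
        participant_id=epochs.participant_id,
        kept_mask=kept_mask & epochs.kept_mask,
        eog=epochs.eog,
        trial_index=epochs.trial_index,
    )
    report = QCReport.from_rates(
        n_trials=n_trials,
        eog_rate=eog_trial.sum() / n_trials,
        emg_rate=emg_trial.sum() / n_trials,
    )
    logger.info(
        "artifact rejection: %d trials, %.1f%% EOG, %.1f%% EMG, %.1f%% preserved",
        n_trials, report.pct_eog_rejected, report.pct_emg_rejected, report.pct_preserved,
    )
    return out, report
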