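"""Synthetic 22-channel + 3-EOG EEG with ground-truth coupling structure.

The generator emulates the statistical structure the downstream analysis
assumes, not the biophysics of the head.  Each coupled electrode pair shares
a latent band-limited oscillator (band-pass-filtered Gaussian noise in the
mu and beta bands, unit variance); every channel additionally carries
independent pink (1/f) noise.  During the 2 s imagery window of a trial, the
mixing weight of each coupled edge is multiplied by that task's
``condition_scale`` — a value below 1 reduces inter-channel coupling for
that task, which is the effect the pipeline is built to detect.  Ocular
(EOG) and muscular (EMG) artifacts are injected on random trials at
configurable rates and recorded in a ground-truth table.

With a single shared oscillator of weight ``w`` on an edge and pink noise of
standard deviation ``sigma`` on each endpoint, the expected zero-lag Pearson
correlation of the two channels is ``w**2 / (w**2 + sigma**2)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from micnet.paradigm import TASK_LABELS, SessionSpec, TrialSchedule

__all__ = [
    "LatentSourceModel",
    "ArtifactModel",
    "Recording",
    "simulate_recording",
    "ground_truth_edges",
    "default_tongue_model",
    "DEFAULT_TONGUE_EDGES",
    "pink_noise",
]

N_EEG = 22
N_EOG = 3

#: Default coupled edges (1-based channel-index pairs): a frontocentral /
#: centroparietal network of 19 pairs whose coupling the tongue task reduces.
DEFAULT_TONGUE_EDGES: tuple[tuple[int, int], ...] = (
    (3, 8), (9, 10), (2, 3), (9, 14), (8, 9), (8, 10), (3, 10),
    (5, 6), (6, 13),
    (3, 4), (4, 8), (3, 11), (4, 9), (10, 11), (4, 12), (1, 12),
    (6, 10), (5, 8), (5, 7),
)


@dataclass(frozen=True)
class LatentSourceModel:
    """Latent coupled-oscillator model of inter-channel dependence.

    Parameters
    ----------
    coupling_edges
        Channel-index pairs (1-based, i < j) sharing a latent oscillator.
    coupling_weight
        Unitless mixing weight of the shared oscillator into both endpoint
        channels.  The default 8 with ``noise_sd`` 10 µV gives a baseline
        zero-lag correlation of 64/164 ≈ 0.39 on coupled pairs.
    condition_scale
        Per-task multiplicative factor applied to ``coupling_weight`` during
        that task's imagery window.  Values in [0, 1]; 1 means no effect.
    bands
        (center_hz, half_bandwidth_hz) pairs of the oscillator spectrum;
        defaults are the mu (10 ± 2 Hz) and beta (20 ± 5 Hz) rhythms.
    noise_sd
        Per-channel pink-noise standard deviation in µV.
    """

    coupling_edges: tuple[tuple[int, int], ...] = DEFAULT_TONGUE_EDGES
    coupling_weight: float = 8.0
    condition_scale: dict[str, float] = field(
        default_factory=lambda: {"tongue": 0.3}
    )
    bands: tuple[tuple[float, float], ...] = ((10.0, 2.0), (20.0, 5.0))
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.coupling_weight < 0:
            raise ValueError("coupling_weight must be >= 0")
        for task, scale in self.condition_scale.items():
            if task not in TASK_LABELS:
                raise ValueError(f"unknown task label {task!r}")
            if not 0.0 <= scale <= 1.0:
                raise ValueError(f"condition_scale[{task!r}] outside [0, 1]")
        for center, half_bw in self.bands:
            if not 1.0 <= center <= 45.0:
                raise ValueError(f"band center {center} Hz outside 1-45 Hz")
            if half_bw <= 0:
                raise ValueError("band half-width must be positive")
        for i, j in self.coupling_edges:
            if not (1 <= i <= N_EEG and 1 <= j <= N_EEG and i != j):
                raise ValueError(f"invalid coupling edge ({i}, {j})")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ArtifactModel:
    """Trial-level artifact injection: rates, amplitudes and bands."""

    eog_trial_rate: float = 0.048
    emg_trial_rate: float = 0.012
    eog_amplitude_uv: float = 150.0
    emg_amplitude_uv: float = 40.0
    eog_band_hz: tuple[float, float] = (0.5, 4.0)
    emg_band_hz: tuple[float, float] = (30.0, 100.0)

    def __post_init__(self) -> None:
        for key in ("eog_trial_rate", "emg_trial_rate"):
            rate = getattr(self, key)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{key} outside [0, 1]")
        for key in ("eog_amplitude_uv", "emg_amplitude_uv"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")


@dataclass
class Recording:
    """One participant-session of continuous multichannel data.

    ``data`` is samples x 25 channels in µV: 22 EEG channels in montage
    order followed by 3 EOG channels.  ``truth`` is a per-trial DataFrame
    with boolean ``eog_artifact`` / ``emg_artifact`` columns aligned with
    ``schedule`` order.
    """

    data: np.ndarray
    sample_rate_hz: float
    schedule: TrialSchedule
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != N_EEG + N_EOG:
            raise ValueError(f"data must be samples x {N_EEG + N_EOG}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        need = int(round(self.schedule.span_s() * self.sample_rate_hz))
        if self.data.shape[0] < need:
            warnings.warn(
                f"recording has {self.data.shape[0]} samples but the schedule "
                f"spans {need}; trailing trials will be dropped at epoching",
                stacklevel=2,
            )

    @property
    def eeg(self) -> np.ndarray:
        return self.data[:, :N_EEG]

    @property
    def eog(self) -> np.ndarray:
        return self.data[:, N_EEG:]

    def save(self, prefix: str | Path) -> None:
        """Write flat little-endian float32 binary + JSON header + events TSV."""
        prefix = Path(prefix)
        raw = self.data.astype("<f4")
        raw.tofile(prefix.with_suffix(".dat"))
        header = {
            "format": "micnet-recording-v1",
            "dtype": "<f4",
            "order": "C",
            "n_samples": int(raw.shape[0]),
            "n_channels": int(raw.shape[1]),
            "n_eeg": N_EEG,
            "n_eog": N_EOG,
            "sample_rate_hz": self.sample_rate_hz,
            "units": "uV",
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))
        self.schedule.to_tsv(prefix.with_suffix(".events.tsv"))
        self.truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str | Path, spec: SessionSpec | None = None) -> "Recording":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        if header.get("format") != "micnet-recording-v1":
            raise ValueError(f"unrecognized recording header at {prefix}")
        data = np.fromfile(prefix.with_suffix(".dat"), dtype=header["dtype"])
        data = data.reshape(header["n_samples"], header["n_channels"]).astype(float)
        schedule = TrialSchedule.from_tsv(prefix.with_suffix(".events.tsv"), spec=spec)
        truth = pd.read_csv(prefix.with_suffix(".truth.tsv"), sep="\t")
        return cls(
            data=data,
            sample_rate_hz=float(header["sample_rate_hz"]),
            schedule=schedule,
            truth=truth,
        )


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    sd: float = 1.0,
    fs: float = 250.0,
    floor_hz: float = 0.5,
) -> np.ndarray:
    """1/f-power noise by spectral shaping of white Gaussian noise.

    The 1/f amplitude law is floored below ``floor_hz`` (default the 0.5 Hz
    acquisition high-pass corner), so the noise carries the recorded band's
    spectral content without unbounded drift.
    """
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], floor_hz))
    shaped = np.fft.irfft(spectrum * scale, n=n_samples)
    shaped_sd = shaped.std()
    if shaped_sd > 0:
        shaped *= sd / shaped_sd
    return shaped


def _band_limited_noise(
    n_samples: int,
    bands: tuple[tuple[float, float], ...],
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance sum of band-pass-filtered white-noise components."""
    out = np.zeros(n_samples)
    for center, half_bw in bands:
        lo = max(center - half_bw, 0.1)
        hi = min(center + half_bw, fs / 2 - 1e-6)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out += signal.sosfilt(sos, rng.standard_normal(n_samples))
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def default_tongue_model(**overrides) -> LatentSourceModel:
    """The study-conditions generator: 19 coupled frontocentral edges whose
    coupling drops to 0.3x during tongue imagery."""
    return LatentSourceModel(**overrides)


def ground_truth_edges(model: LatentSourceModel, task_label: str) -> set[tuple[int, int]]:
    """Edges whose effective coupling during ``task_label`` differs from baseline."""
    if task_label not in TASK_LABELS:
        raise ValueError(f"unknown task label {task_label!r}")
    if model.condition_scale.get(task_label, 1.0) == 1.0:
        return set()
    return {(min(i, j), max(i, j)) for i, j in model.coupling_edges}


def simulate_recording(
    schedule: TrialSchedule,
    model: LatentSourceModel | None = None,
    artifacts: ArtifactModel | None = None,
    seed: int = 0,
) -> Recording:
    """Simulate one participant-session of continuous 25-channel data.

    ``schedule`` must contain a single participant and session (use
    ``TrialSchedule.subset``).  The same seed gives bit-identical output.
    """
    model = model or LatentSourceModel()
    artifacts = artifacts or ArtifactModel()
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    if len(schedule.participants) != 1 or len(schedule.sessions) != 1:
        raise ValueError(
            "simulate_recording expects a single participant-session schedule; "
            "use schedule.subset(participant_id=..., session_index=...)"
        )
    spec = schedule.spec
    fs = spec.sample_rate_hz
    n_samples = int(round(schedule.span_s() * fs))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=int(seed) & 0x7FFFFFFF,
            spawn_key=(schedule.participants[0], schedule.sessions[0]),
        )
    )

    data = np.zeros((n_samples, N_EEG + N_EOG))
    for ch in range(N_EEG):
        data[:, ch] = pink_noise(n_samples, rng, sd=model.noise_sd)

    # Per-edge time-varying coupling gain: 1 outside imagery, condition_scale
    # during the imagery window of a task the model modulates.
    gain = np.ones(n_samples)
    windows: list[tuple[int, int, float]] = []
    for event in schedule:
        scale = model.condition_scale.get(event.task_label, 1.0)
        if scale != 1.0:
            start = int(round((event.onset_s + spec.fixation_s + spec.cue_s) * fs))
            stop = min(start + int(round(spec.imagery_s * fs)), n_samples)
            windows.append((start, stop, scale))
    for start, stop, scale in windows:
        gain[start:stop] = scale

    for i, j in model.coupling_edges:
        source = _band_limited_noise(n_samples, model.bands, fs, rng)
        contribution = model.coupling_weight * gain * source
        data[:, i - 1] += contribution
        data[:, j - 1] += contribution

    # EOG channels: shared ocular source (slow band) scaled per channel + noise.
    eog_center = (artifacts.eog_band_hz[0] + artifacts.eog_band_hz[1]) / 2
    eog_half = (artifacts.eog_band_hz[1] - artifacts.eog_band_hz[0]) / 2
    ocular = _band_limited_noise(n_samples, ((eog_center, eog_half),), fs, rng)
    eog_gains = (1.0, 0.8, 0.6)
    for k in range(N_EOG):
        data[:, N_EEG + k] = 15.0 * eog_gains[k] * ocular + pink_noise(
            n_samples, rng, sd=5.0
        )

    # Artifact injection per trial.
    n_trials = len(schedule)
    eog_flags = rng.random(n_trials) < artifacts.eog_trial_rate
    emg_flags = rng.random(n_trials) < artifacts.emg_trial_rate
    trial_len = int(round((spec.fixation_s + spec.cue_s + spec.imagery_s) * fs))
    for t, event in enumerate(schedule):
        start = int(round(event.onset_s * fs))
        stop = min(start + trial_len, n_samples)
        seg = stop - start
        if eog_flags[t]:
            burst = _band_limited_noise(seg, ((eog_center, eog_half),), fs, rng)
            burst *= artifacts.eog_amplitude_uv / max(np.abs(burst).max(), 1e-12)
            for k in range(N_EOG):
                data[start:stop, N_EEG + k] += eog_gains[k] * burst
            # Frontal leakage into EEG (rows 1-6 are frontocentral).
            data[start:stop, :6] += 0.3 * burst[:, None]
        if emg_flags[t]:
            # Independent broadband high-frequency noise on every EEG channel.
            sos = signal.butter(
                4,
                [artifacts.emg_band_hz[0], min(artifacts.emg_band_hz[1], fs / 2 - 1e-6)],
                btype="bandpass", fs=fs, output="sos",
            )
            burst_block = signal.sosfilt(
                sos, rng.standard_normal((seg, N_EEG)), axis=0
            )
            rms = burst_block.std()
            if rms > 0:
                burst_block *= artifacts.emg_amplitude_uv / rms
            data[start:stop, :N_EEG] += burst_block

    truth = schedule.to_frame()
    truth["eog_artifact"] = eog_flags
    truth["emg_artifact"] = emg_flags
    active = sorted(ground_truth_edges(model, "tongue")) if model.condition_scale else []
    truth.attrs["modulated_edges"] = active
    return Recording(
        data=data, sample_rate_hz=fs, schedule=schedule, truth=truth
    )
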