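"""Pairwise association: cross-correlation adjacency, z-normalization,
complex-demodulation coherence, and threshold graphs.

The condition adjacency matrix is the 22x22 matrix of zero-lag Pearson
correlation coefficients between channel pairs, estimated per 500-sample
epoch and averaged across kept epochs through the Fisher z-transform
(atanh, mean, tanh).  A max-lag variant reports, per pair, the absolute
maximum of the cross-correlation function over lags |l| <= L, signed by the
correlation at the maximizing lag.

Coherence is computed by complex demodulation: each channel is mixed with a
complex exponential at -f for every f on a 0.5 Hz grid, low-pass filtered,
and resampled on a 100 ms grid; the magnitude-squared coherence at (f, t)
is |<X conj(Y)>|^2 / (<|X|^2> <|Y|^2>) with <.> the mean over epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from micnet.paradigm import Montage, standard_montage
from micnet.preprocess import EpochSet

__all__ = [
    "ConnectivityMatrix",
    "CoherenceSpectrum",
    "crosscorr_matrix",
    "zscore_matrices",
    "demodulation_coherence",
    "threshold_graph",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels association matrix.

    ``kind`` tags the scale of the entries: 'r' (correlation), 'z'
    (normalized score), 't', 'p', 'q' or 'coherence'.  The diagonal is 1
    for 'r'/'coherence' and is ignored for the statistical kinds.
    """

    values: np.ndarray
    kind: str = "r"
    condition: str = ""
    participant_id: int | str = "group"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i<j) entries as a flat vector."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path, montage: Montage | None = None) -> None:
        montage = montage or standard_montage()
        names = list(montage.channels)[: self.n_channels]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.6g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "r", **kw) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=float), kind=kind, **kw)


@dataclass
class CoherenceSpectrum:
    """Coherence of one channel pair on a frequency x time grid in [0, 1]."""

    values: np.ndarray  # freq x time
    freq_axis: np.ndarray  # Hz, 0.5 Hz steps
    time_axis: np.ndarray  # s, 100 ms steps
    pair: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freq_axis), len(self.time_axis)):
            raise ValueError("values shape must match (freq, time) axes")


def _epoch_correlations(data: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlation matrices per epoch.

    data: epochs x channels x samples -> epochs x channels x channels, with
    NaN where a channel is constant within the epoch.
    """
    x = data - data.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    cov = np.einsum("ecs,eds->ecd", x, x) / x.shape[-1]
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    corr[denom == 0] = np.nan
    return np.clip(corr, -1.0, 1.0)


def _maxlag_correlations(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Per epoch, max-|r| cross-correlation over lags |l| <= max_lag,
    signed by the correlation at the maximizing lag."""
    n_epochs, n_ch, n_s = data.shape
    out = np.full((n_epochs, n_ch, n_ch), np.nan)
    for e in range(n_epochs):
        x = data[e] - data[e].mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1)
        for i in range(n_ch):
            out[e, i, i] = 1.0 if sd[i] > 0 else np.nan
            for j in range(i + 1, n_ch):
                if sd[i] == 0 or sd[j] == 0:
                    continue
                cc = signal.correlate(x[i], x[j], mode="full") / (n_s * sd[i] * sd[j])
                mid = n_s - 1
                window = cc[mid - max_lag : mid + max_lag + 1]
                best = window[np.argmax(np.abs(window))]
                out[e, i, j] = out[e, j, i] = np.clip(best, -1.0, 1.0)
    return out


def crosscorr_matrix(
    epochs: EpochSet,
    condition: str,
    max_lag: int = 0,
    kept_only: bool = True,
) -> ConnectivityMatrix:
    """Condition adjacency: Fisher-z-averaged per-epoch correlations.

    ``max_lag`` = 0 (default) gives the zero-lag Pearson coefficient;
    ``max_lag`` = L > 0 switches to the signed max-absolute cross-correlation
    over lags |l| <= L.  Epochs where a pair is undefined (constant channel)
    are excluded from that pair's mean; a pair undefined in every epoch is an
    error.
    """
    data = epochs.select(condition, kept_only=kept_only)
    if data.shape[0] < 2:
        raise ValueError(
            f"need >= 2 kept epochs of condition {condition!r}, have {data.shape[0]}"
        )
    if max_lag == 0:
        corr = _epoch_correlations(data)
    else:
        corr = _maxlag_correlations(data, max_lag)
    # Fisher-z average; clip keeps atanh finite for |r| ~ 1.
    z = np.arctanh(np.clip(corr, -0.999999, 0.999999))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_z = np.nanmean(z, axis=0)
    iu = np.triu_indices(mean_z.shape[0], k=1)
    if np.isnan(mean_z[iu]).any():
        raise ValueError("pair(s) undefined in every epoch; cannot average")
    values = np.tanh(mean_z)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2
    return ConnectivityMatrix(
        values=values, kind="r", condition=condition,
        participant_id=epochs.participant_id,
    )


def zscore_matrices(
    matrices: list[ConnectivityMatrix],
    target_variance: float = 1.0,
) -> list[ConnectivityMatrix]:
    """Per-participant affine normalization of pooled off-diagonal entries.

    All matrices in the list must belong to one participant; their pooled
    off-diagonal entries are rescaled to mean 0 and ``target_variance``
    (population convention), and the identical affine map is applied to
    every matrix.  ``target_variance=3.0`` is provided as a fidelity mode.
    """
    if not matrices:
        return []
    pids = {m.participant_id for m in matrices}
    if len(pids) > 1:
        raise ValueError(f"matrices from multiple participants: {sorted(map(str, pids))}")
    pooled = np.concatenate([m.offdiag() for m in matrices])
    mu = pooled.mean()
    sd = pooled.std()  # population (ddof=0)
    if sd == 0:
        raise ValueError("zero pooled variance; cannot normalize")
    scale = np.sqrt(target_variance) / sd
    out = []
    for m in matrices:
        values = (m.values - mu) * scale
        np.fill_diagonal(values, 0.0)
        out.append(
            ConnectivityMatrix(
                values=values, kind="z", condition=m.condition,
                participant_id=m.participant_id,
            )
        )
    return out


def _demodulate(
    data: np.ndarray, freqs: np.ndarray, fs: float, step_samples: int
) -> np.ndarray:
    """Complex envelopes: epochs x channels x freqs x time_points.

    Mixes with exp(-i 2 pi f t) and low-pass filters the product with a
    zero-phase Butterworth whose cutoff matches the 0.5 Hz grid spacing,
    then subsamples every ``step_samples``.
    """
    n_epochs, n_ch, n_s = data.shape
    t = np.arange(n_s) / fs
    # 0.25 Hz transition to match the 0.5 Hz frequency grid.  On short
    # epochs the zero-phase IIR needs a reduced pad length.
    sos = signal.butter(2, 0.25, btype="lowpass", fs=fs, output="sos")
    padlen = min(3 * (2 * 2 + 1), n_s - 1)
    idx = np.arange(0, n_s, step_samples)
    out = np.empty((n_epochs, n_ch, len(freqs), len(idx)), dtype=complex)
    for k, f in enumerate(freqs):
        mixer = np.exp(-2j * np.pi * f * t)
        mixed = data * mixer  # broadcast over epochs/channels
        env = signal.sosfiltfilt(sos, mixed.real, axis=-1, padlen=padlen) + 1j * (
            signal.sosfiltfilt(sos, mixed.imag, axis=-1, padlen=padlen)
        )
        out[:, :, k, :] = env[..., idx]
    return out


def demodulation_coherence(
    epochs: EpochSet,
    pair: tuple[int, int],
    condition: str | None = None,
    band: tuple[float, float] = (1.0, 45.0),
    sample_rate_hz: float = 250.0,
    freq_step_hz: float = 0.5,
    time_step_s: float = 0.1,
    kept_only: bool = True,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence of one channel pair on a 0.5 Hz x 100 ms grid.

    ``pair`` holds 1-based channel indices.  Requires at least 8 kept
    epochs; fewer epochs leave the cross-epoch expectation too noisy to be
    meaningful.
    """
    if not (0.0 < band[0] < band[1] < sample_rate_hz / 2):
        raise ValueError(f"band {band} outside (0, {sample_rate_hz / 2}) Hz")
    if condition is None:
        data = epochs.epochs[epochs.kept_mask] if kept_only else epochs.epochs
    else:
        data = epochs.select(condition, kept_only=kept_only)
    if data.shape[0] < 8:
        raise ValueError(f"need >= 8 kept epochs, have {data.shape[0]}")
    i, j = pair
    pair_data = data[:, [i - 1, j - 1], :]
    freqs = np.arange(band[0], band[1] + freq_step_hz / 2, freq_step_hz)
    step_samples = int(round(time_step_s * sample_rate_hz))
    env = _demodulate(pair_data, freqs, sample_rate_hz, step_samples)
    x, y = env[:, 0], env[:, 1]  # epochs x freq x time
    cross = np.mean(x * np.conj(y), axis=0)
    px = np.mean(np.abs(x) ** 2, axis=0)
    py = np.mean(np.abs(y) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / (px * py)
    coh = np.where((px > 0) & (py > 0), coh, 0.0)
    time_axis = np.arange(coh.shape[1]) * time_step_s
    return CoherenceSpectrum(
        values=np.clip(coh, 0.0, 1.0), freq_axis=freqs, time_axis=time_axis,
        pair=(i, j),
    )


def threshold_graph(matrix: ConnectivityMatrix, r_threshold: float):
    """Binarize an 'r' or 'coherence' matrix into a simple undirected graph.

    Edge (i, j), i < j, exists iff the matrix value is >= ``r_threshold``.
    Returns a :class:`micnet.graphstats.SignificanceGraph`.
    """
    from micnet.graphstats import SignificanceGraph

    if matrix.kind not in ("r", "coherence"):
        raise ValueError(f"thresholding requires kind 'r' or 'coherence', got {matrix.kind!r}")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold {r_threshold} outside (0, 1)")
    n = matrix.n_channels
    edges = {
        (i + 1, j + 1)
        for i in range(n)
        for j in range(i + 1, n)
        if matrix.values[i, j] >= r_threshold
    }
    return SignificanceGraph(n_vertices=n, edges=frozenset(edges))
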