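"""Raw EMG to activation-matrix preprocessing.

The chain is the standard linear-envelope pipeline: zero-lag band-pass
(30–400 Hz, 4th-order Butterworth), full-wave rectification, zero-lag
low-pass (6 Hz, 4th-order Butterworth), cropping to one gait cycle,
time-normalisation to a fixed number of points (200), and per-muscle peak
amplitude normalisation.  The output is an L×N matrix with entries in [0, 1]
and each non-zero row peaking at exactly 1 — the muscle activation patterns
that every factorisation method consumes.

All filters are applied forward–backward (``sosfiltfilt``), so the envelope
is phase-lag free; the filter is designed at order 4 and the effective
attenuation is doubled by the two passes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawEMGTrial",
    "ActivationMatrix",
    "bandpass",
    "linear_envelope",
    "normalise_trial",
    "process_trial",
]

logger = logging.getLogger(__name__)

DEFAULT_BANDPASS = (30.0, 400.0)
DEFAULT_ENVELOPE_CUTOFF = 6.0
DEFAULT_N_POINTS = 200
_FILTER_ORDER = 4


@dataclasses.dataclass
class RawEMGTrial:
    """One trial of raw multi-channel EMG.

    ``events`` holds (start_sample, end_sample) of the gait cycle, inclusive.
    """

    signal: np.ndarray  # L x S, volts (arbitrary gain)
    fs: float
    events: tuple[int, int]
    channel_labels: list[str]
    condition: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        start, end = self.events
        if not (0 <= start < end <= self.signal.shape[1]):
            raise ValueError("events must satisfy 0 <= start < end <= n_samples")
        if self.fs <= 2 * DEFAULT_BANDPASS[1]:
            raise ValueError("sampling rate must exceed twice the band-pass upper edge")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclasses.dataclass
class ActivationMatrix:
    """Normalised muscle activation patterns (L muscles x N time points)."""

    x: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-D")
        if len(self.channel_labels) != self.x.shape[0]:
            raise ValueError("one label per muscle required")

    @property
    def L(self) -> int:
        return self.x.shape[0]

    @property
    def N(self) -> int:
        return self.x.shape[1]


def _butter_sos(fs: float, cutoff, btype: str) -> np.ndarray:
    return sps.butter(_FILTER_ORDER, cutoff, btype=btype, fs=fs, output="sos")


def bandpass(
    signal: np.ndarray,
    fs: float,
    low: float = DEFAULT_BANDPASS[0],
    high: float = DEFAULT_BANDPASS[1],
) -> np.ndarray:
    """Zero-lag 4th-order Butterworth band-pass, per channel."""
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError("band-pass upper edge must be below the Nyquist frequency")
    sos = _butter_sos(fs, (low, high), "bandpass")
    return sps.sosfiltfilt(sos, np.atleast_2d(signal), axis=-1)


def bandpass_response_db(fs: float, freq: float, low: float = DEFAULT_BANDPASS[0],
                         high: float = DEFAULT_BANDPASS[1]) -> float:
    """Magnitude response (dB) of the zero-lag band-pass at ``freq`` Hz.

    Accounts for the forward–backward double pass (squared magnitude).
    """
    sos = _butter_sos(fs, (low, high), "bandpass")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(20.0 * np.log10(np.abs(h[0]) ** 2))


def linear_envelope(
    signal: np.ndarray,
    fs: float,
    lowpass_cutoff: float = DEFAULT_ENVELOPE_CUTOFF,
) -> np.ndarray:
    """Full-wave rectification followed by a zero-lag Butterworth low-pass.

    Negative ripples introduced by the sharp low-pass are clipped at zero so
    the envelope is a valid non-negative activation-intensity estimate.
    """
    if not (0 < lowpass_cutoff < fs / 2):
        raise ValueError("lowpass_cutoff must be in (0, fs/2)")
    sos = _butter_sos(fs, lowpass_cutoff, "lowpass")
    env = sps.sosfiltfilt(sos, np.abs(np.atleast_2d(signal)), axis=-1)
    return np.clip(env, 0.0, None)


def normalise_trial(
    envelope: np.ndarray,
    events: tuple[int, int],
    n_points: int = DEFAULT_N_POINTS,
    per_muscle: bool = True,
) -> ActivationMatrix:
    """Crop to the gait cycle, time-normalise, peak-normalise.

    Each channel is linearly interpolated onto ``n_points`` uniformly spaced
    points of normalised cycle time, then divided by its own peak
    (``per_muscle=True``) or by the global trial peak.  All-zero channels are
    left as zeros and logged, not treated as errors.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    start, end = events
    if end - start < 2:
        raise ValueError("event span must cover at least 2 samples")
    cropped = envelope[:, start : end + 1]

    src = np.linspace(0.0, 1.0, cropped.shape[1])
    dst = np.linspace(0.0, 1.0, n_points)
    resampled = np.empty((cropped.shape[0], n_points))
    for ch in range(cropped.shape[0]):
        resampled[ch] = np.interp(dst, src, cropped[ch])

    if per_muscle:
        peaks = resampled.max(axis=1, keepdims=True)
    else:
        peaks = np.full((cropped.shape[0], 1), resampled.max())
    dead = np.flatnonzero(peaks.ravel() <= 0)
    if dead.size:
        logger.warning("channels %s are identically zero; left unnormalised", dead.tolist())
    np.divide(resampled, peaks, out=resampled, where=peaks > 0)

    labels = [f"ch{c + 1:02d}" for c in range(resampled.shape[0])]
    return ActivationMatrix(x=resampled, channel_labels=labels)


def process_trial(
    trial: RawEMGTrial,
    bandpass_low_hz: float = DEFAULT_BANDPASS[0],
    bandpass_high_hz: float = DEFAULT_BANDPASS[1],
    envelope_cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF,
    n_points: int = DEFAULT_N_POINTS,
    per_muscle: bool = True,
) -> ActivationMatrix:
    """Full chain: band-pass → rectify+low-pass → crop/resample/normalise."""
    filtered = bandpass(trial.signal, trial.fs, bandpass_low_hz, bandpass_high_hz)
    env = linear_envelope(filtered, trial.fs, envelope_cutoff_hz)
    act = normalise_trial(env, trial.events, n_points=n_points, per_muscle=per_muscle)
    act.channel_labels = list(trial.channel_labels)
    return act
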