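"""Synthetic gait-EMG generation.

Real surface-EMG recordings of walking and running are characterised here by
two statistical features that downstream analyses depend on:

* the amplitude distribution of the raw (band-limited, zero-mean) signal,
  whose excess kurtosis decreases with gait speed — from roughly Laplacian-like
  (~1.75 after envelope modulation) in walking towards Gaussian-like (~1.0) in
  fast running;
* burst-like per-muscle activity envelopes locked to the gait cycle, which is
  what makes a small number of muscle synergies a good low-rank description.

Both are emulated by multiplying a white generalized-Gaussian carrier with a
per-channel gait envelope (tonic baseline plus 1–3 Gaussian bursts).  The
carrier's shape parameter β interpolates between Laplacian (β = 1, excess
kurtosis 3) and Gaussian (β = 2, excess kurtosis 0); it is calibrated per
channel so that the *sample* kurtosis of the enveloped signal matches the
requested speed-condition target, using the closed-form GGD moments plus a
delta-method correction for the finite-sample bias of the pooled kurtosis
estimator (bursty envelopes concentrate the fourth moment in few samples, so
the naive plug-in calibration over-shoots).

Ground-truth synergy datasets (`generate_synergy_dataset`) build activation
matrices x = W·H + ε directly from non-negative weights and smooth burst
primitives, for parameter-recovery and VAF testing.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .preprocessing import RawEMGTrial, ActivationMatrix

__all__ = [
    "SpeedCondition",
    "SPEED_CONDITIONS",
    "SynergyGroundTruth",
    "sample_generalized_gaussian",
    "generate_raw_trial",
    "generate_synergy_dataset",
]


@dataclasses.dataclass(frozen=True)
class SpeedCondition:
    """A locomotion speed condition and its raw-EMG distribution target.

    Parameters
    ----------
    label:
        One of ``walk``, ``slow_run``, ``moderate_run``, ``fast_run``.
    target_excess_kurtosis:
        Pooled excess kurtosis (Fisher convention, Gaussian = 0) that raw
        trials generated under this condition should exhibit.
    cycle_duration:
        Duration of one gait cycle (toe-off to toe-off), seconds.
    """

    label: str
    target_excess_kurtosis: float
    cycle_duration: float

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")


#: The four speed conditions, ordered from walking to fast running. Kurtosis
#: targets follow the observed decrease with speed; cycle durations are
#: typical stride times at ~1.3 / 3 / 5 / 7 m/s.
SPEED_CONDITIONS: dict[str, SpeedCondition] = {
    "walk": SpeedCondition("walk", 1.75, 1.08),
    "slow_run": SpeedCondition("slow_run", 1.45, 0.78),
    "moderate_run": SpeedCondition("moderate_run", 1.29, 0.62),
    "fast_run": SpeedCondition("fast_run", 1.10, 0.52),
}


@dataclasses.dataclass(frozen=True)
class SynergyGroundTruth:
    """Known non-negative factors behind a simulated activation matrix."""

    W_true: np.ndarray  # L x K_true, non-negative weights
    H_true: np.ndarray  # K_true x N, non-negative, peak-normalised rows
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.W_true < 0) or np.any(self.H_true < 0):
            raise ValueError("ground-truth factors must be non-negative")


# ---------------------------------------------------------------------------
# generalized Gaussian carrier


def _gg_abs_moment(beta: float, p: float) -> float:
    """Standardised (unit-variance) absolute moment E|X|^p of a GGD."""
    return (
        special.gamma((p + 1) / beta)
        * special.gamma(1 / beta) ** (p / 2 - 1)
        / special.gamma(3 / beta) ** (p / 2)
    )


def gg_excess_kurtosis(beta: float) -> float:
    """Closed-form excess kurtosis of a generalized Gaussian with shape β."""
    return _gg_abs_moment(beta, 4.0) - 3.0


_BETA_LO, _BETA_HI = 0.3, 30.0


def _beta_for_population_kurtosis(k: float) -> float:
    """Invert β from a target population excess kurtosis (clamped to range)."""
    k = float(np.clip(k, gg_excess_kurtosis(_BETA_HI) + 1e-6, gg_excess_kurtosis(_BETA_LO) - 1e-6))
    return optimize.brentq(lambda b: gg_excess_kurtosis(b) - k, _BETA_LO, _BETA_HI)


def _sample_kurtosis_bias(beta: float, envelope: np.ndarray) -> float:
    """Delta-method bias of the sample kurtosis of an envelope-modulated GGD.

    For s_t = e_t·c_t with c iid unit-variance GGD, the plug-in kurtosis
    m4/m2² is biased upward because m4 and m2 are estimated from the same
    (effectively few, burst-dominated) samples.  Second-order Taylor expansion
    of E[m4/m2²] around the population moments gives the correction used here.
    """
    S = envelope.size
    q2 = float(np.mean(envelope**2))
    q4 = float(np.mean(envelope**4))
    q6 = float(np.mean(envelope**6))
    m4 = _gg_abs_moment(beta, 4.0)
    m6 = _gg_abs_moment(beta, 6.0)
    base = q4 * m4 / q2**2
    var_m2 = (q4 / S) * (m4 - 1.0)
    cov_m4_m2 = (q6 / S) * (m6 - m4)
    return base * (3.0 * var_m2 / q2**2 - 2.0 * cov_m4_m2 / (q4 * m4 * q2))


def _calibrate_beta(target_excess: float, envelope: np.ndarray) -> float:
    """Choose β so the enveloped signal's *sample* kurtosis hits the target.

    Two-step: solve the exact population equation (target+3)/r = m4(β), where
    r = mean(e⁴)/mean(e²)² is the envelope kurtosis-inflation factor, then
    re-solve with the delta-method finite-sample bias subtracted from the
    target.
    """
    r = float(np.mean(envelope**4) / np.mean(envelope**2) ** 2)
    beta0 = _beta_for_population_kurtosis((target_excess + 3.0) / r - 3.0)
    bias = _sample_kurtosis_bias(beta0, envelope)
    return _beta_for_population_kurtosis((target_excess - bias + 3.0) / r - 3.0)


def sample_generalized_gaussian(
    n: int, shape_beta: float, scale: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Draw n iid zero-mean generalized-Gaussian variates.

    β = 1 is Laplacian (excess kurtosis 3), β = 2 Gaussian (0).  ``scale`` is
    the GGD scale parameter α, not the standard deviation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if shape_beta <= 0 or scale <= 0:
        raise ValueError("shape_beta and scale must be positive")
    rng = np.random.default_rng(seed)
    return stats.gennorm.rvs(shape_beta, scale=scale, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# raw trials

_ENV_BASELINE = 0.5
_ENV_WIDTH = (0.10, 0.18)  # burst sd, fraction of cycle
_ENV_AMP = (0.7, 1.1)
_MAX_BURSTS = 3


def _channel_envelope(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Tonic baseline plus 1–3 Gaussian bursts; one channel's gait envelope.

    Always consumes a fixed number of draws so the carrier stream stays
    aligned across conditions sharing a seed.
    """
    n_bursts = int(rng.integers(1, _MAX_BURSTS + 1))
    env = np.full(t.size, _ENV_BASELINE)
    for j in range(_MAX_BURSTS):
        centre = rng.uniform(0.05, 0.95)
        width = rng.uniform(*_ENV_WIDTH)
        amp = rng.uniform(*_ENV_AMP)
        if j < n_bursts:
            env += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return env


def generate_raw_trial(
    condition: SpeedCondition | str,
    n_channels: int = 10,
    fs: float = 1500.0,
    seed: int = 0,
) -> RawEMGTrial:
    """Simulate one gait cycle of multi-channel raw EMG.

    Each channel is a white generalized-Gaussian carrier modulated by a
    burst-like gait envelope; β is calibrated per channel so the pooled
    excess kurtosis of the trial matches the condition target.  Channel
    streams are spawned from the master seed with one child per channel, so
    changing ``n_channels`` never reshuffles existing channels.
    """
    if isinstance(condition, str):
        condition = SPEED_CONDITIONS[condition]
    if fs < 800.0:
        raise ValueError("fs must be >= 800 Hz (band-pass upper edge 400 Hz would alias)")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")

    children = np.random.SeedSequence(seed).spawn(n_channels)
    n_samples = int(round(condition.cycle_duration * fs))
    t = np.arange(n_samples) / n_samples
    signal = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        rng = np.random.default_rng(children[ch])
        env = _channel_envelope(rng, t)
        beta = _calibrate_beta(condition.target_excess_kurtosis, env)
        # inverse-CDF sampling: the same uniforms give comonotone carriers
        # across conditions, which stabilises the cross-speed kurtosis ordering
        u = rng.random(n_samples)
        carrier = stats.gennorm.ppf(u, beta) / stats.gennorm.std(beta)
        s = env * carrier
        signal[ch] = s / np.sqrt(np.mean(s**2))

    return RawEMGTrial(
        signal=signal,
        fs=float(fs),
        events=(0, n_samples - 1),
        channel_labels=[f"ch{c + 1:02d}" for c in range(n_channels)],
        condition=condition.label,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth synergy datasets

_BURST_WIDTH = (0.04, 0.06)  # primitive burst sd, fraction of cycle
_CENTRE_JITTER = 0.04
_DOMINANT_WEIGHT = (0.7, 1.0)
_CROSS_WEIGHT = 0.15


def generate_synergy_dataset(
    L: int = 10,
    K_true: int = 3,
    N: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[SynergyGroundTruth, ActivationMatrix]:
    """Build an activation matrix from known non-negative synergies.

    H_true rows are smooth Gaussian bursts spread over the cycle; W_true gives
    each muscle one dominant synergy plus small cross-loadings.  The product
    plus truncated Gaussian noise is row-peak-normalised, matching the
    preprocessing output contract (values in [0, 1], row max 1).
    """
    if K_true >= L:
        raise ValueError("K_true must be < L")
    if N < 2:
        raise ValueError("N must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    t = np.arange(N) / N

    H = np.zeros((K_true, N))
    for k in range(K_true):
        centre = (k + 0.5) / K_true + rng.uniform(-_CENTRE_JITTER, _CENTRE_JITTER)
        width = rng.uniform(*_BURST_WIDTH)
        H[k] = np.exp(-0.5 * ((t - centre) / width) ** 2)
        H[k] /= H[k].max()

    W = np.zeros((L, K_true))
    for l in range(L):
        dominant = l % K_true
        for k in range(K_true):
            if k == dominant:
                W[l, k] = rng.uniform(*_DOMINANT_WEIGHT)
            else:
                W[l, k] = rng.uniform(0.0, _CROSS_WEIGHT)

    X = W @ H
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(L, N))
    X = np.clip(X, 0.0, None)
    peaks = X.max(axis=1, keepdims=True)
    np.divide(X, peaks, out=X, where=peaks > 0)

    truth = SynergyGroundTruth(W_true=W, H_true=H, noise_sd=float(noise_sd), seed=int(seed))
    activation = ActivationMatrix(x=X, channel_labels=[f"m{l + 1:02d}" for l in range(L)])
    return truth, activation


def condition_sequence() -> Sequence[SpeedCondition]:
    """Conditions in increasing-speed order (decreasing kurtosis target)."""
    return list(SPEED_CONDITIONS.values())
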