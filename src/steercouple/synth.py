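"""Synthetic steering sessions: wheel angle, deltoid/forearm EMG, EEG.

The generator emulates the signal structure the downstream analysis relies
on: smooth sigmoid wheel excursions to about +/-90 deg; broadband
(20-200 Hz) surface-EMG whose contralateral deltoid bursts slightly before
the wheel leaves zero; and a sensor-mixed EEG in which a 10 Hz source with
a left centro-parietal topography desynchronizes well before left steering
(mu event-related desynchronization), next to an occipital 10 Hz distractor
and per-channel 1/f noise. Every trial carries ground truth so each
pipeline stage can be tested as a recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import (
    DIRECTION_SIGN,
    EpochSet,
    InvalidParameterError,
    WheelTrace,
)

#: contralateral deltoid drives the wheel (anterior portion rotates it
#: contralaterally), so left steering is powered by the right deltoid
EMG_CHANNELS = ["delt_l", "delt_r", "forearm_l", "forearm_r"]
CONTRA_DELTOID = {"left": "delt_r", "right": "delt_l"}
IPSI_DELTOID = {"left": "delt_l", "right": "delt_r"}

_RAMP_STEEPNESS = 6.0  # logistic slope over the normalized rise interval


@dataclass
class SessionSpec:
    """Parameters of one synthetic recording session."""

    n_trials_left: int = 44
    n_trials_right: int = 44
    fs: float = 500.0
    emg_lead: float = 0.2  # s the deltoid burst precedes the wheel onset
    eeg_lead: float = 1.5  # s the mu desynchronization precedes the onset
    erd_depth: float = 0.5  # fraction of mu amplitude suppressed
    emg_snr: float = 12.0  # dB, burst-window RMS over baseline RMS
    eeg_snr: float = 10.0  # dB, mu RMS over 1/f noise RMS at the peak channel
    n_eeg_channels: int = 32
    seed: int = 0
    # wheel excursion shape ("quiet pace": ~2.2 s total, holds past the
    # [-2, 2] s trial end so the whole-trial chord stays informative)
    peak_angle: float = 90.0
    rise: float = 0.5
    plateau: float = 1.2
    fall: float = 0.5
    wheel_noise_sd: float = 0.5  # deg, additive sensor noise
    burst_duration: float = 1.5  # s of sustained deltoid activity
    erd_duration_post: float = 1.0  # s the ERD persists after onset
    ipsi_suppression: float = 0.3  # mild amplitude drop of the ipsilateral deltoid
    mu_freq: float = 10.0
    osc_bandwidth: float = 2.0  # Hz, bandwidth of the mu/alpha oscillations
    burstiness: float = 0.5  # log-amplitude sd of the slow waxing/waning envelope

    def __post_init__(self) -> None:
        if self.n_trials_left + self.n_trials_right <= 0:
            raise InvalidParameterError("need at least one trial")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise InvalidParameterError("erd_depth must be in [0, 1]")
        if self.emg_lead < 0 or self.eeg_lead < 0:
            raise InvalidParameterError("leads must be non-negative")
        if self.n_eeg_channels < 3:
            raise InvalidParameterError(
                "n_eeg_channels must be >= 3 (two mapped sources plus noise)"
            )


@dataclass
class GroundTruth:
    """Per-trial truth: onsets (ramp support start), directions, effect windows."""

    onsets: np.ndarray
    directions: np.ndarray
    burst_windows: dict[str, list[tuple[float, float] | None]] = field(default_factory=dict)
    erd_windows: list[tuple[float, float] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.directions = np.asarray(self.directions, dtype=object)
        if self.onsets.size != self.directions.size:
            raise InvalidParameterError("one direction per onset required")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise InvalidParameterError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class Session:
    """Continuous synthetic records plus ground truth."""

    wheel: WheelTrace
    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    eeg_ch_names: list[str]
    emg_ch_names: list[str]
    truth: GroundTruth
    spec: SessionSpec

    @property
    def duration(self) -> float:
        return self.wheel.duration


# ---------------------------------------------------------------------------
# primitives


def _truncated_logistic(u: np.ndarray) -> np.ndarray:
    """Logistic ramp rescaled to hit exactly 0 at u=0 and 1 at u=1."""
    s = 1.0 / (1.0 + np.exp(-_RAMP_STEEPNESS * (np.clip(u, 0, 1) - 0.5)))
    s0 = 1.0 / (1.0 + np.exp(_RAMP_STEEPNESS / 2))
    return (s - s0) / (1.0 - 2.0 * s0)


def excursion_profile(
    t: np.ndarray, onset: float, rise: float, plateau: float, fall: float
) -> np.ndarray:
    """Unsigned 0 -> 1 -> 0 excursion with sigmoid ramps; exactly 0 outside."""
    out = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    out[up] = _truncated_logistic((t[up] - onset) / rise)
    flat = (t >= onset + rise) & (t < onset + rise + plateau)
    out[flat] = 1.0
    down = (t >= onset + rise + plateau) & (t < onset + rise + plateau + fall)
    out[down] = _truncated_logistic(1.0 - (t[down] - onset - rise - plateau) / fall)
    return out


def smooth_gate(t: np.ndarray, t0: float, t1: float, edge: float = 0.1) -> np.ndarray:
    """0 -> 1 -> 0 gate over [t0, t1] with logistic edges of width ``edge``."""
    if edge <= 0:
        return ((t >= t0) & (t <= t1)).astype(float)
    up = _truncated_logistic((t - t0) / edge)
    down = np.where(t <= t1, 1.0, _truncated_logistic(1.0 - (t - t1) / edge))
    return up * down


def ramp_threshold_crossing(spec: SessionSpec, threshold: float = 2.0) -> float:
    """Time after the true onset at which the ramp crosses ``threshold`` deg."""
    u = np.linspace(0.0, 1.0, 20001)
    g = _truncated_logistic(u)
    idx = int(np.searchsorted(g, threshold / abs(spec.peak_angle)))
    return u[idx] * spec.rise


def gen_wheel_trace(
    direction: str,
    onset: float,
    peak_angle: float = 90.0,
    fs: float = 500.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    duration: float = 4.0,
    rise: float = 0.5,
    plateau: float = 1.2,
    fall: float = 0.5,
) -> WheelTrace:
    """One signed sigmoid/plateau/return excursion plus sensor noise.

    The noise is applied in the signed frame, so ``left`` and ``right``
    traces generated from the same rng state are exact negations.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if peak_angle == 0:
        raise InvalidParameterError("peak_angle must be nonzero")
    if rise + plateau + fall < 0.5:
        raise InvalidParameterError("excursion must last at least 0.5 s")
    t = np.arange(int(round(duration * fs))) / fs
    profile = abs(peak_angle) * excursion_profile(t, onset, rise, plateau, fall)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        profile = profile + rng.normal(0.0, noise_sd, size=t.size)
    return WheelTrace(DIRECTION_SIGN[direction] * profile, fs=fs)


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, band=(20.0, 200.0)
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (surface-EMG surrogate).

    A two-second warm-up is generated and discarded so the causal filter
    transient never reaches the returned samples.
    """
    hi = min(band[1], 0.99 * fs / 2)
    sos = scipy.signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    w, h = scipy.signal.sosfreqz(sos, worN=4096, fs=fs)
    gain = np.sqrt(np.mean(np.abs(h) ** 2))
    pad = int(2 * fs)
    padded = shape[:-1] + (shape[-1] + pad,)
    x = scipy.signal.sosfilt(sos, rng.standard_normal(padded), axis=-1)[..., pad:]
    return x / gain


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """Unit-variance 1/f noise, FFT-shaped, flat below 1 Hz."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = amp * (
        rng.standard_normal(shape[:-1] + (freqs.size,))
        + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))
    )
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# idealized sensor layout and forward maps


def ideal_layout(n_channels: int) -> np.ndarray:
    """(n, 2) sunflower layout on the unit disk; x: left(-) to right(+), y: posterior(-) to anterior(+)."""
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * 2.399963229728653  # golden angle
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


_SOURCE_CENTERS = {"mu": (-0.35, -0.15), "occipital": (0.0, -0.75)}
_SOURCE_SIGMA = {"mu": 0.5, "occipital": 0.4}


def forward_maps(n_channels: int) -> np.ndarray:
    """(n_channels, 2) mixing matrix: smooth 2-D Gaussian topographies for
    the mu (left centro-parietal) and occipital sources, peak-normalized."""
    pos = ideal_layout(n_channels)
    cols = []
    for name in ("mu", "occipital"):
        c = np.asarray(_SOURCE_CENTERS[name])
        d2 = ((pos - c) ** 2).sum(axis=1)
        m = np.exp(-d2 / (2 * _SOURCE_SIGMA[name] ** 2))
        cols.append(m / m.max())
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# trial-level generators (window [-2.5, 2.5) s around the event)

_TRIAL_WINDOW = (-2.5, 2.5)


def _emg_signals(
    directions,
    onsets: np.ndarray,
    spec: SessionSpec,
    rng: np.random.Generator,
    n_samples: int,
    t: np.ndarray,
) -> np.ndarray:
    """Continuous 4-channel EMG with per-trial deltoid bursts."""
    x = _bandlimited_noise(rng, (len(EMG_CHANNELS), n_samples), spec.fs)
    burst_amp = np.sqrt(max(10.0 ** (spec.emg_snr / 10.0) - 1.0, 0.0))
    for onset, direction in zip(onsets, directions):
        t0 = onset - spec.emg_lead
        env = smooth_gate(t, t0, t0 + spec.burst_duration, edge=0.1)
        if burst_amp > 0:
            contra = EMG_CHANNELS.index(CONTRA_DELTOID[direction])
            x[contra] += burst_amp * env * _bandlimited_noise(rng, (n_samples,), spec.fs)
        ipsi = EMG_CHANNELS.index(IPSI_DELTOID[direction])
        x[ipsi] *= 1.0 - spec.ipsi_suppression * env
    return x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, f0: float, bw: float
) -> np.ndarray:
    """Unit-variance stochastic oscillation: white noise band-passed around
    f0, with a discarded warm-up so the filter transient is not returned."""
    sos = scipy.signal.butter(
        4, [max(f0 - bw / 2, 0.1), f0 + bw / 2], btype="bandpass", fs=fs, output="sos"
    )
    pad = int(4 * fs)
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _bursty_envelope(
    rng: np.random.Generator, n: int, fs: float, strength: float
) -> np.ndarray:
    """Unit-mean log-normal slow envelope (waxing/waning of a rhythm)."""
    if strength <= 0:
        return np.ones(n)
    slow = _pink_noise(rng, (n,), fs)
    k = max(int(fs), 1)
    slow = np.convolve(slow, np.ones(k) / k, mode="same")
    sd = slow.std()
    slow = slow / (sd if sd > 0 else 1.0)
    return np.exp(strength * slow - strength**2 / 2.0)


def _eeg_signals(
    directions,
    onsets: np.ndarray,
    spec: SessionSpec,
    rng: np.random.Generator,
    n_samples: int,
    t: np.ndarray,
) -> np.ndarray:
    """Continuous EEG: forward-mixed mu + occipital sources plus 1/f noise.

    Both rhythms are stochastic narrowband oscillations with independent
    slow waxing/waning envelopes (as cortical alpha-band rhythms are),
    which makes them mutually independent and super-Gaussian -- the
    conditions ICA needs. The mu source additionally carries the
    event-related desynchronization envelope on left-steering trials.
    """
    maps = forward_maps(spec.n_eeg_channels)
    amp = np.ones(n_samples)
    for onset, direction in zip(onsets, directions):
        if direction != "left":
            continue
        t0 = onset - spec.eeg_lead
        amp = amp * (1.0 - spec.erd_depth * smooth_gate(t, t0, onset + spec.erd_duration_post))
    s_mu = (
        amp
        * _bursty_envelope(rng, n_samples, spec.fs, spec.burstiness)
        * _narrowband_noise(rng, n_samples, spec.fs, spec.mu_freq, spec.osc_bandwidth)
    )
    s_occ = (
        0.8
        * _bursty_envelope(rng, n_samples, spec.fs, spec.burstiness)
        * _narrowband_noise(rng, n_samples, spec.fs, spec.mu_freq, spec.osc_bandwidth)
    )
    noise_sd = 10.0 ** (-spec.eeg_snr / 20.0)
    noise = noise_sd * _pink_noise(rng, (spec.n_eeg_channels, n_samples), spec.fs)
    return maps @ np.vstack([s_mu, s_occ]) + noise


def gen_emg_trial(
    direction: str, onset: float, spec: SessionSpec, rng: np.random.Generator
) -> EpochSet:
    """One 4-channel EMG trial cut [-2.5, 2.5) s around ``onset``.

    Baseline is 20-200 Hz band-limited noise of unit variance; the
    contralateral deltoid carries a sustained burst starting at
    ``onset - emg_lead`` whose amplitude makes the burst-window RMS exceed
    baseline RMS by ``emg_snr`` dB; the ipsilateral deltoid is mildly
    suppressed; forearm channels carry no direction-dependent modulation.
    """
    n = int(round((_TRIAL_WINDOW[1] - _TRIAL_WINDOW[0]) * spec.fs))
    t = onset + _TRIAL_WINDOW[0] + np.arange(n) / spec.fs
    x = _emg_signals([direction], np.array([onset]), spec, rng, n, t)
    return EpochSet(
        x[None], spec.fs, _TRIAL_WINDOW, list(EMG_CHANNELS), np.array([direction], object)
    )


def gen_eeg_trial(
    direction: str, onset: float, spec: SessionSpec, rng: np.random.Generator
) -> EpochSet:
    """One EEG trial cut [-2.5, 2.5) s around ``onset``.

    Sensor signals are a fixed forward mixture (see :func:`forward_maps`) of
    a mu-band source whose amplitude drops by ``erd_depth`` from
    ``onset - eeg_lead`` on left trials, an occipital direction-invariant
    distractor, and per-channel 1/f noise.
    """
    n = int(round((_TRIAL_WINDOW[1] - _TRIAL_WINDOW[0]) * spec.fs))
    t = onset + _TRIAL_WINDOW[0] + np.arange(n) / spec.fs
    x = _eeg_signals([direction], np.array([onset]), spec, rng, n, t)
    names = [f"eeg{i:03d}" for i in range(spec.n_eeg_channels)]
    return EpochSet(x[None], spec.fs, _TRIAL_WINDOW, names, np.array([direction], object))


# ---------------------------------------------------------------------------
# full session


def gen_session(spec: SessionSpec) -> Session:
    """Continuous wheel/EEG/EMG records with randomized inter-trial gaps >= 3 s.

    All randomness is drawn from a single generator seeded by ``spec.seed``;
    per-trial sub-streams are spawned deterministically.
    """
    root = np.random.SeedSequence(spec.seed)
    s_order, s_iti, s_wheel, s_emg, s_eeg = root.spawn(5)
    rng_order = np.random.default_rng(s_order)

    n_trials = spec.n_trials_left + spec.n_trials_right
    directions = np.array(
        ["left"] * spec.n_trials_left + ["right"] * spec.n_trials_right, object
    )
    rng_order.shuffle(directions)

    exc_dur = spec.rise + spec.plateau + spec.fall
    # quiet gaps of 8-10 s leave room for non-steering epochs clear of the
    # next trial's EEG/EMG lead-in while keeping the >= 3 s invariant
    gaps = exc_dur + 8.0 + np.random.default_rng(s_iti).uniform(0.0, 2.0, size=n_trials)
    onsets = 5.0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    duration = onsets[-1] + exc_dur + 5.0
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs

    wheel = np.zeros(n)
    for onset, direction in zip(onsets, directions):
        wheel += (
            DIRECTION_SIGN[direction]
            * abs(spec.peak_angle)
            * excursion_profile(t, onset, spec.rise, spec.plateau, spec.fall)
        )
    if spec.wheel_noise_sd > 0:
        wheel += np.random.default_rng(s_wheel).normal(0, spec.wheel_noise_sd, size=n)

    emg = _emg_signals(directions, onsets, spec, np.random.default_rng(s_emg), n, t)
    eeg = _eeg_signals(directions, onsets, spec, np.random.default_rng(s_eeg), n, t)

    burst_windows: dict[str, list] = {name: [None] * n_trials for name in EMG_CHANNELS}
    erd_windows: list = [None] * n_trials
    for i, (onset, direction) in enumerate(zip(onsets, directions)):
        contra = CONTRA_DELTOID[direction]
        burst_windows[contra][i] = (onset - spec.emg_lead, onset - spec.emg_lead + spec.burst_duration)
        if direction == "left":
            erd_windows[i] = (onset - spec.eeg_lead, onset + spec.erd_duration_post)

    truth = GroundTruth(onsets, directions, burst_windows, erd_windows)
    return Session(
        wheel=WheelTrace(wheel, fs=spec.fs),
        eeg=eeg,
        emg=emg,
        fs=spec.fs,
        eeg_ch_names=[f"eeg{i:03d}" for i in range(spec.n_eeg_channels)],
        emg_ch_names=list(EMG_CHANNELS),
        truth=truth,
        spec=spec,
    )
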