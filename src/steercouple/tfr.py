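"""Morlet-wavelet time-frequency decomposition (ERSP).

Two preset grids are used throughout: EEG power on 38 linearly spaced
frequencies from 2 to 40 Hz with 3 to 12 wavelet cycles, and EMG power on
198 linearly spaced frequencies from 2 to 200 Hz with 3 to 60 cycles, the
cycle ramp linear in frequency index. Output panels are sampled every
10 ms, the hop that makes a 0.5 s window exactly 50 columns and a 3 s
window exactly 300 columns. ERSP is a single-trial divisive baseline:
per trial and frequency the power is divided by its mean baseline power,
converted to dB, and only then averaged across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import DegenerateInputError, EpochSet, InvalidParameterError


@dataclass
class TFGrid:
    """Frequency grid with a per-frequency wavelet-cycle ramp."""

    freqs: np.ndarray
    cycles: np.ndarray
    hop: float = 0.01  # s between output columns (100 columns/s)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=float)
        if self.freqs.size != self.cycles.size:
            raise InvalidParameterError("freqs and cycles must have equal length")
        if self.freqs.size and np.any(np.diff(self.freqs) <= 0):
            raise InvalidParameterError("freqs must be strictly increasing")
        if np.any(self.cycles < 3):
            raise InvalidParameterError("cycles must be >= 3")

    @classmethod
    def eeg_preset(cls) -> "TFGrid":
        """2-40 Hz in 38 linear steps, 3-12 cycles."""
        return cls(np.linspace(2.0, 40.0, 38), np.linspace(3.0, 12.0, 38))

    @classmethod
    def emg_preset(cls) -> "TFGrid":
        """2-200 Hz in 198 linear steps, 3-60 cycles."""
        return cls(np.linspace(2.0, 200.0, 198), np.linspace(3.0, 60.0, 198))


@dataclass
class TFPanel:
    """Time-frequency values on an explicit (freqs, times) grid.

    ``values`` is trials x freqs x times for per-trial power, or
    freqs x times for a trial-averaged dB panel; ``units`` tells which.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    units: str = "power"  # "power" | "dB"
    baseline_window: tuple[float, float] | None = None
    edge_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.units not in ("power", "dB"):
            raise InvalidParameterError("units must be 'power' or 'dB'")
        if self.values.shape[-2:] != (self.freqs.size, self.times.size):
            raise InvalidParameterError("values shape must end in (n_freqs, n_times)")
        if self.units == "power" and np.any(self.values < 0):
            raise InvalidParameterError("power panels must be non-negative")
        if self.units == "dB" and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("dB panels must be finite")

    @property
    def hop(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan


def morlet_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized so a unit-amplitude
    sinusoid at ``freq`` yields |convolution| = 1 (support +/- 4 sigma)."""
    sigma = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2.0 * sigma**2))
    w = env * np.exp(2j * np.pi * freq * t)
    return w * (2.0 / env.sum())


def morlet_power(
    epochs: EpochSet, grid: TFGrid, channel: int | str | None = None
) -> TFPanel:
    """Per-trial wavelet power of one channel on ``grid``.

    Convolves each trial with complex Morlet wavelets (|.|^2), sampled every
    ``grid.hop`` seconds. Samples closer to an epoch edge than half the
    wavelet support are flagged in ``edge_mask`` (freqs x times, True =
    edge-contaminated). Raises if the epoch is shorter than the wavelet at
    the lowest grid frequency.
    """
    if channel is None:
        if epochs.n_channels != 1:
            raise InvalidParameterError("channel required for multichannel epochs")
        channel = 0
    if isinstance(channel, str):
        channel = epochs.channel(channel)
    x = epochs.values[:, channel, :]
    fs = epochs.fs

    wavelets = [morlet_wavelet(f, c, fs) for f, c in zip(grid.freqs, grid.cycles)]
    longest = max(w.size for w in wavelets)
    if longest > epochs.n_samples:
        raise InvalidParameterError(
            f"epoch of {epochs.n_samples} samples is shorter than the "
            f"{longest}-sample wavelet at {grid.freqs[0]:.3g} Hz; need at least "
            f"{longest / fs:.2f} s"
        )

    hop_n = grid.hop * fs
    if abs(hop_n - round(hop_n)) > 1e-9:
        raise InvalidParameterError(f"hop {grid.hop} s is not an integer number of samples at fs={fs}")
    hop_n = int(round(hop_n))
    col_idx = np.arange(0, epochs.n_samples, hop_n)
    times = epochs.window[0] + col_idx / fs

    power = np.empty((epochs.n_trials, grid.freqs.size, col_idx.size))
    edge = np.zeros((grid.freqs.size, col_idx.size), dtype=bool)
    for k, w in enumerate(wavelets):
        conv = scipy.signal.fftconvolve(x, w[None, :], mode="same", axes=1)
        power[:, k, :] = np.abs(conv[:, col_idx]) ** 2
        half = w.size // 2
        edge[k] = (col_idx < half) | (col_idx >= epochs.n_samples - half)
    return TFPanel(power, grid.freqs.copy(), times, units="power", edge_mask=edge)


def baseline_db(
    panel: TFPanel,
    baseline_window: tuple[float, float] = (-0.5, -0.1),
    keep_trials: bool = False,
) -> TFPanel:
    """Single-trial divisive dB baseline.

    Per trial and frequency the power is divided by its mean over the
    half-open ``baseline_window``. With ``keep_trials`` each trial's
    normalized power is converted to dB individually; otherwise the
    normalized power is averaged across trials first and converted once,
    so a stationary process reads 0 dB everywhere (taking the log before
    averaging would bias every cell by the mean-log/log-mean gap of the
    power distribution, about -2.5 dB for near-exponential power). The
    default window is the cue-locked [-0.5, -0.1] s convention;
    onset-locked panels use [-2, 2] s.
    """
    if panel.units != "power" or panel.values.ndim != 3:
        raise InvalidParameterError("baseline_db needs a per-trial power panel")
    b0, b1 = baseline_window
    cols = (panel.times >= b0 - 1e-9) & (panel.times < b1 - 1e-9)
    if not cols.any():
        raise InvalidParameterError(
            f"baseline window {baseline_window} outside panel times "
            f"[{panel.times[0]:.3g}, {panel.times[-1]:.3g}]"
        )
    base = panel.values[:, :, cols].mean(axis=2, keepdims=True)
    floor = 1e-12 * max(panel.values.max(), 1e-300)
    if np.any(base <= floor):
        raise DegenerateInputError("zero baseline power in at least one trial/frequency")
    ratio = panel.values / base
    if keep_trials:
        db = 10.0 * np.log10(ratio + 1e-300)
    else:
        db = 10.0 * np.log10(ratio.mean(axis=0) + 1e-300)
    return TFPanel(
        db,
        panel.freqs.copy(),
        panel.times.copy(),
        units="dB",
        baseline_window=baseline_window,
        edge_mask=None if panel.edge_mask is None else panel.edge_mask.copy(),
    )


def panel_window(
    panel: TFPanel,
    freq_range: tuple[float, float] | None = None,
    time_range: tuple[float, float] | None = None,
) -> TFPanel:
    """Rectangular sub-panel.

    Frequencies are selected from the bin nearest the lower bound to the
    bin nearest the upper bound, inclusive (so [8, 20] Hz on the EEG preset
    keeps 13 rows); times follow the half-open [t0, t1) convention (so
    [-1.5, -1) keeps 50 columns at the 10 ms hop). Raises on an empty
    selection.
    """
    vals = panel.values
    freqs = panel.freqs
    times = panel.times
    edge = panel.edge_mask

    if freq_range is not None:
        i0 = int(np.argmin(np.abs(freqs - freq_range[0])))
        i1 = int(np.argmin(np.abs(freqs - freq_range[1])))
        if i1 < i0:
            raise InvalidParameterError("empty frequency selection")
        vals = vals[..., i0 : i1 + 1, :]
        if edge is not None:
            edge = edge[i0 : i1 + 1, :]
        freqs = freqs[i0 : i1 + 1]
    if time_range is not None:
        hop = panel.hop
        j0 = int(round((time_range[0] - times[0]) / hop))
        j1 = int(round((time_range[1] - times[0]) / hop))
        j0 = max(j0, 0)
        j1 = min(j1, times.size)
        if j1 <= j0:
            raise InvalidParameterError("empty time selection")
        vals = vals[..., j0:j1]
        if edge is not None:
            edge = edge[:, j0:j1]
        times = times[j0:j1]
    return TFPanel(
        vals.copy(),
        freqs.copy(),
        times.copy(),
        units=panel.units,
        baseline_window=panel.baseline_window,
        edge_mask=edge,
    )
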