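"""Signal cleaning: line-noise suppression, re-referencing, trial rejection.

Line noise at the mains fundamental and its harmonics is removed by
sliding-window sinusoid regression: within each window the signal is
regressed on sine/cosine pairs at the exact harmonic frequencies and the
fitted narrowband component subtracted. Unlike a notch filter this leaves
broadband (EMG) power untouched outside the regressed lines.

Artifact rejection replaces a manual screening step with a fully automatic
robust-z rule on per-trial linear trends and band-power profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .containers import EpochSet, InvalidParameterError

log = logging.getLogger(__name__)


def suppress_line_noise(
    signal: np.ndarray,
    fs: float,
    fundamental: float = 50.0,
    n_harmonics: int = 5,
    window_s: float = 1.0,
) -> np.ndarray:
    """Regress out the first ``n_harmonics`` multiples of ``fundamental``.

    Operates on the last axis in windows of ``window_s`` seconds with a
    continuous global phase, so stationary mains interference cancels
    almost exactly while power more than a few Hz away is left within a
    fraction of a dB. Harmonics at or above the Nyquist frequency are
    dropped with a warning.
    """
    x = np.asarray(signal, dtype=float)
    freqs = fundamental * np.arange(1, n_harmonics + 1)
    reachable = freqs < fs / 2
    if not reachable.all():
        log.warning(
            "dropping %d harmonic(s) at or above Nyquist (%.1f Hz)",
            int((~reachable).sum()),
            fs / 2,
        )
        freqs = freqs[reachable]
    if freqs.size == 0:
        return x.copy()

    n = x.shape[-1]
    flat = x.reshape(-1, n)
    out = flat.copy()
    win = max(int(round(window_s * fs)), 4 * freqs.size + 2)
    t = np.arange(n) / fs
    starts = list(range(0, n, win))
    for s in starts:
        e = min(s + win, n)
        if e - s < 2 * freqs.size + 2:  # fold a short tail into the previous fit
            if s == 0:
                break
            continue
        if n - e < 2 * freqs.size + 2:
            e = n
        tw = t[s:e]
        basis = np.empty((e - s, 2 * freqs.size))
        for k, f in enumerate(freqs):
            basis[:, 2 * k] = np.sin(2 * np.pi * f * tw)
            basis[:, 2 * k + 1] = np.cos(2 * np.pi * f * tw)
        coef, *_ = np.linalg.lstsq(basis, flat[:, s:e].T, rcond=None)
        out[:, s:e] = flat[:, s:e] - (basis @ coef).T
        if e == n:
            break
    return out.reshape(x.shape)


def common_average_reference(data: EpochSet | np.ndarray) -> EpochSet | np.ndarray:
    """Subtract the instantaneous mean across channels (zero-mean montage)."""
    if isinstance(data, EpochSet):
        vals = data.values - data.values.mean(axis=1, keepdims=True)
        return EpochSet(vals, data.fs, data.window, list(data.ch_names), data.event_labels)
    x = np.asarray(data, dtype=float)
    ch_axis = 0 if x.ndim == 2 else 1
    return x - x.mean(axis=ch_axis, keepdims=True)


@dataclass
class RejectionReport:
    """Outcome of automatic trial screening."""

    kept: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.kept.size

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_rejected(self) -> int:
        return self.n_total - self.n_kept


def _robust_z(features: np.ndarray) -> np.ndarray:
    """Robust z-scores across the first (trial) axis.

    Centers are per-channel medians across trials; the scale is a single
    median/MAD estimate pooled over trials and channels (per trailing
    feature axis, if any), which keeps the tail of the null z distribution
    honest where per-channel MADs from few trials would not.
    """
    med = np.median(features, axis=0, keepdims=True)
    resid = features - med
    mad = scipy.stats.median_abs_deviation(
        resid.reshape(-1, *features.shape[2:]), axis=0, scale="normal"
    )
    mad = np.where(mad == 0, np.inf, mad)
    return resid / mad


_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 100.0))


def reject_artifact_trials(
    epochs: EpochSet, trend_z: float = 5.0, spectrum_z: float = 5.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials with abnormal linear trends or band-power profiles.

    Per trial and channel, the slope of a linear fit and the log band powers
    (delta through gamma) are converted to robust z-scores across trials;
    a trial is rejected when any channel exceeds ``trend_z`` (slope) or
    ``spectrum_z`` (any band). Rejection is equivariant under trial
    reordering. Raises if every trial would be rejected.
    """
    if epochs.n_trials < 5:
        raise InvalidParameterError("need at least 5 trials for robust screening")
    x = epochs.values
    t = epochs.times
    tc = t - t.mean()
    slopes = (x * tc).sum(axis=2) / (tc**2).sum()  # trials x channels

    # short segments with overlap: enough averaging that log band powers
    # are close to Gaussian across trials (keeps robust-z tails honest)
    nperseg = min(epochs.n_samples, max(int(epochs.fs // 4), 16))
    f, psd = scipy.signal.welch(x, fs=epochs.fs, nperseg=nperseg, axis=2)
    band_power = np.stack(
        [
            np.log10(psd[:, :, (f >= lo) & (f < min(hi, epochs.fs / 2))].mean(axis=2) + 1e-30)
            for lo, hi in _BANDS
            if ((f >= lo) & (f < min(hi, epochs.fs / 2))).any()
        ],
        axis=2,
    )  # trials x channels x bands

    z_trend = np.abs(_robust_z(slopes))
    z_spec = np.abs(_robust_z(band_power))
    bad_trend = z_trend.max(axis=1) > trend_z
    bad_spec = z_spec.max(axis=(1, 2)) > spectrum_z
    kept = ~(bad_trend | bad_spec)
    if not kept.any():
        raise InvalidParameterError(
            "all trials rejected; review trend_z/spectrum_z thresholds"
        )
    reasons = {}
    for i in np.flatnonzero(~kept):
        parts = []
        if bad_trend[i]:
            parts.append(f"trend z={z_trend[i].max():.1f}")
        if bad_spec[i]:
            parts.append(f"spectrum z={z_spec[i].max():.1f}")
        reasons[int(i)] = ", ".join(parts)
        log.info("trial %d rejected (%s)", i, reasons[int(i)])
    report = RejectionReport(
        kept=kept,
        reasons=reasons,
        thresholds={"trend_z": trend_z, "spectrum_z": spectrum_z},
    )
    return epochs.pick(np.flatnonzero(kept)), report
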