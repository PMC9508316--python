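"""EEG-EMG coupling by full 2-D cross-correlation of ERSP panels.

The subject- and condition-specific EEG template ("mask") is the dB ERSP
sub-panel over roughly 8-20 Hz and [-1.5, -1) s before the steering onset
(13 x 50 under the preset grids). It is cross-correlated, unnormalized and
in full mode, against each single-trial EMG ERSP panel over [-1, 2) s
(198 x 300), giving a 210 x 349 lag matrix whose first 12 rows (mask
sliding below the panel's lowest frequency) are discarded, leaving
198 x 349. Trial matrices are averaged within subject, pairing mask and
EMG panels of the same steering condition.

Two null constructions probe specificity: a half-split of non-steering
trials into pseudo-left/right conditions, and a label shuffle of the
steering trials; both are repeated over seeded iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.signal

from .containers import InvalidParameterError
from .tfr import TFPanel, panel_window

log = logging.getLogger(__name__)

MASK_FREQ_RANGE = (8.0, 20.0)
MASK_TIME_RANGE = (-1.5, -1.0)
EMG_TIME_RANGE = (-1.0, 2.0)
N_TRIM_ROWS = 12


@dataclass
class Mask:
    """Rectangular EEG ERSP template over the group-significant window."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidParameterError("mask must be a non-empty 2-D panel")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("mask values must be finite")


@dataclass
class XCorrMatrix:
    """Full 2-D cross-correlation output in (frequency-lag, time-lag) space."""

    values: np.ndarray
    row_lags: np.ndarray  # frequency-bin lags
    col_lags: np.ndarray  # time-bin lags
    provenance: dict = field(default_factory=dict)


def extract_mask(
    panel: TFPanel,
    freq_range: tuple[float, float] = MASK_FREQ_RANGE,
    time_range: tuple[float, float] = MASK_TIME_RANGE,
) -> Mask:
    """Cut the coupling template out of a subject's dB ERSP panel."""
    sub = panel_window(panel, freq_range=freq_range, time_range=time_range)
    if sub.values.ndim != 2:
        raise InvalidParameterError("extract_mask expects a trial-averaged panel")
    return Mask(sub.values, sub.freqs, sub.times)


def xcorr2(
    mask: Mask | np.ndarray, panel: np.ndarray, normalized: bool = False
) -> XCorrMatrix:
    """Full 2-D cross-correlation of ``mask`` against ``panel``.

    out[i, j] = sum_{u,v} mask[u, v] * panel[u + i - (M-1), v + j - (N-1)]
    for an M x N mask, with out-of-range panel indices contributing zero;
    the output is (P+M-1) x (Q+N-1) for a P x Q panel (e.g. 13 x 50 against
    198 x 300 gives 210 x 349). The published pairing applies no mean
    removal or scaling (the default); ``normalized=True`` gives a globally
    normalized variant -- both inputs demeaned and the output divided by
    the product of their Frobenius norms, making it invariant to affine
    rescaling of either input. Integer inputs are computed exactly
    (direct summation).
    """
    m = np.asarray(mask.values if isinstance(mask, Mask) else mask)
    p = np.asarray(panel)
    if m.size == 0 or p.size == 0 or m.ndim != 2 or p.ndim != 2:
        raise InvalidParameterError("mask and panel must be non-empty 2-D arrays")
    if normalized:
        m = m - m.mean()
        p = p - p.mean()
        scale = np.linalg.norm(m) * np.linalg.norm(p)
        if scale == 0:
            raise InvalidParameterError("normalized xcorr2 of a constant input")
        m = m / scale
    exact = (
        not normalized
        and np.issubdtype(m.dtype, np.integer)
        and np.issubdtype(p.dtype, np.integer)
    )
    out = scipy.signal.correlate(p, m, mode="full", method="direct" if exact else "fft")
    M, N = m.shape
    P, Q = p.shape
    return XCorrMatrix(
        values=out,
        row_lags=np.arange(-(M - 1), P),
        col_lags=np.arange(-(N - 1), Q),
    )


def trim_nonsignificant_rows(xc: XCorrMatrix, n_rows: int = N_TRIM_ROWS) -> XCorrMatrix:
    """Drop the first ``n_rows`` rows (mask overhanging below the panel)."""
    if not 0 <= n_rows < xc.values.shape[0]:
        raise InvalidParameterError(
            f"n_rows={n_rows} outside [0, {xc.values.shape[0] - 1}]"
        )
    return XCorrMatrix(
        values=xc.values[n_rows:],
        row_lags=xc.row_lags[n_rows:],
        col_lags=xc.col_lags.copy(),
        provenance=dict(xc.provenance),
    )


def xcorr_times(xc: XCorrMatrix, panel_t0: float, hop: float) -> np.ndarray:
    """Panel time of the mask origin for each cross-correlation column."""
    return panel_t0 + xc.col_lags * hop


def trial_coupling(
    mask: Mask, trial_panels: np.ndarray, n_trim: int = N_TRIM_ROWS
) -> XCorrMatrix:
    """Trial-by-trial cross-correlation, trimmed, averaged across trials.

    ``trial_panels`` is trials x freqs x times of single-trial dB ERSP.
    Cross-correlation is linear in the panel, so the trial average of the
    per-trial matrices equals the matrix of the trial-averaged panel; the
    latter is computed.
    """
    tp = np.asarray(trial_panels, dtype=float)
    if tp.ndim != 3 or tp.shape[0] == 0:
        raise InvalidParameterError("trial_panels must be non-empty trials x freqs x times")
    return trim_nonsignificant_rows(xcorr2(mask, tp.mean(axis=0)), n_trim)


def coupling_panels(
    masks: dict[str, dict[str, Mask]],
    emg_trials: dict[str, dict[str, dict[str, np.ndarray]]],
    n_trim: int = N_TRIM_ROWS,
) -> dict[str, dict[tuple[str, str], XCorrMatrix]]:
    """Per-subject mean cross-correlation per (muscle, condition).

    ``masks[subject][condition]`` is the EEG template; ``emg_trials
    [subject][muscle][condition]`` is trials x freqs x times of single-trial
    EMG dB ERSP. Pairing is same-condition (left mask with left-steering
    EMG). Subjects missing a mask or an EMG condition are excluded with a
    log message.
    """
    out: dict[str, dict[tuple[str, str], XCorrMatrix]] = {}
    for subject, muscles in emg_trials.items():
        if subject not in masks:
            log.info("subject %s excluded: no EEG mask", subject)
            continue
        per_subj: dict[tuple[str, str], XCorrMatrix] = {}
        complete = True
        for muscle, conds in muscles.items():
            for cond, trials in conds.items():
                if cond not in masks[subject]:
                    log.info("subject %s excluded: no %s mask", subject, cond)
                    complete = False
                    break
                xc = trial_coupling(masks[subject][cond], trials, n_trim)
                xc.provenance = {"subject": subject, "muscle": muscle, "condition": cond}
                per_subj[(muscle, cond)] = xc
            if not complete:
                break
        if complete:
            out[subject] = per_subj
    return out


def _default_stat(left: np.ndarray, right: np.ndarray) -> float:
    return float(np.mean(left - right))


def halfsplit_null(
    nonsteer_trials: dict[str, dict[str, np.ndarray]],
    masks: dict[str, dict[str, Mask]],
    n_iter: int = 300,
    seed: int = 0,
    n_trim: int = N_TRIM_ROWS,
    stat: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> dict[str, np.ndarray]:
    """Half-split pseudo-steering null ensemble.

    Per iteration, each subject's non-steering trials
    (``nonsteer_trials[subject][muscle]``, trials x freqs x times) are
    shuffled; only the first half is used, split into pseudo-left and
    pseudo-right sets that are cross-correlated with the subject's left and
    right masks respectively. ``stat`` reduces the group-mean pseudo-left
    and pseudo-right matrices (default: mean difference); the ensemble per
    muscle has shape (n_iter, ...). Per-iteration seeds derive from the
    master ``seed``.
    """
    stat = stat or _default_stat
    muscles = sorted({m for subj in nonsteer_trials.values() for m in subj})
    out = {m: [] for m in muscles}
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        for muscle in muscles:
            lefts, rights = [], []
            for subject, per_muscle in nonsteer_trials.items():
                if muscle not in per_muscle or subject not in masks:
                    continue
                trials = per_muscle[muscle]
                n = trials.shape[0]
                perm = rng.permutation(n)
                half = perm[: n // 2]
                pseudo_left = half[: half.size // 2]
                pseudo_right = half[half.size // 2 :]
                if pseudo_left.size == 0 or pseudo_right.size == 0:
                    raise InvalidParameterError("too few non-steering trials to half-split")
                lefts.append(
                    trial_coupling(masks[subject]["left"], trials[pseudo_left], n_trim).values
                )
                rights.append(
                    trial_coupling(masks[subject]["right"], trials[pseudo_right], n_trim).values
                )
            out[muscle].append(stat(np.mean(lefts, axis=0), np.mean(rights, axis=0)))
    return {m: np.asarray(v) for m, v in out.items()}


def shuffle_null(
    emg_trials: dict[str, dict[str, dict[str, np.ndarray]]],
    masks: dict[str, dict[str, Mask]],
    n_iter: int = 300,
    seed: int = 0,
    n_trim: int = N_TRIM_ROWS,
    stat: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> dict[str, np.ndarray]:
    """Label-shuffle pseudo-steering null ensemble.

    Per iteration, each subject's left and right steering trials are pooled
    and randomly reassigned to pseudo-left/right sets of the original
    sizes, then processed as in :func:`halfsplit_null`.
    """
    stat = stat or _default_stat
    muscles = sorted({m for subj in emg_trials.values() for m in subj})
    out = {m: [] for m in muscles}
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        for muscle in muscles:
            lefts, rights = [], []
            for subject, per_muscle in emg_trials.items():
                if muscle not in per_muscle or subject not in masks:
                    continue
                conds = per_muscle[muscle]
                pool = np.concatenate([conds["left"], conds["right"]], axis=0)
                n_left = conds["left"].shape[0]
                perm = rng.permutation(pool.shape[0])
                lefts.append(
                    trial_coupling(masks[subject]["left"], pool[perm[:n_left]], n_trim).values
                )
                rights.append(
                    trial_coupling(masks[subject]["right"], pool[perm[n_left:]], n_trim).values
                )
            out[muscle].append(stat(np.mean(lefts, axis=0), np.mean(rights, axis=0)))
    return {m: np.asarray(v) for m, v in out.items()}
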