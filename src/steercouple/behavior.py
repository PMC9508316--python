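"""Steering-onset detection and epoching from wheel-angle traces.

Two onset algorithms are provided. The chord-distance method refines a
per-trial wheel trace: the first stretch of samples exceeding a +/-2 deg
threshold is located, and the onset is the sample of that stretch farthest
from the chord joining the first and last sample of the whole trial (time
and angle normalized to unit range so the maximizer is scale invariant).
The quantize/binarize method works on the continuous record: the wheel
signal is snapped to levels spaced at a fraction of its min-max range,
binarized against the level nearest zero, and each 0 -> 1 transition is an
onset, with direction taken from the sign of the angle just after it.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    DegenerateInputError,
    EpochSet,
    EventTable,
    InvalidParameterError,
    WheelTrace,
)

log = logging.getLogger(__name__)


def _suprathreshold_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of consecutive True samples."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``max_gap`` samples."""
    merged = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return merged


def detect_onset_chord(
    trace: WheelTrace,
    threshold: float = 2.0,
    min_prominence: float = 0.0,
    ambiguous: str = "discard",
    merge_gap: float = 0.2,
) -> float | None:
    """Chord-distance steering onset within a trial trace, or None.

    The first contiguous segment of |angle| > ``threshold`` (default the
    +/-2 deg convention) identifies the excursion; the onset is the sample,
    between the trial start and the excursion peak, maximizing the
    perpendicular distance to the chord joining those two points, computed
    in unit-normalized (time, |angle|) coordinates so the maximizer is
    scale invariant and symmetric under sign flips. For a flat-then-ramp
    trace this is the breakpoint where the movement leaves baseline. Ties
    go to the earliest sample. Returns None (trial discarded) when there is
    no threshold crossing, when the trial is ambiguous (more than one
    disjoint suprathreshold segment, if ``ambiguous='discard'``), or when
    the best distance falls below ``min_prominence``.
    """
    if ambiguous not in ("discard", "first"):
        raise InvalidParameterError("ambiguous must be 'discard' or 'first'")
    x = trace.samples
    mask = np.abs(x) > threshold
    runs = _suprathreshold_runs(mask)
    if not runs:
        return None
    # noise flicker at the slow threshold crossing splits the excursion
    # into micro-runs; only well-separated segments flag real ambiguity
    runs = _merge_runs(runs, max(int(round(merge_gap * trace.fs)), 1))
    if ambiguous == "discard" and len(runs) > 1:
        log.info("ambiguous trial: %d disjoint suprathreshold segments", len(runs))
        return None

    # curve of interest: trial start up to the excursion peak; chord joins
    # its first and last sample in unit-normalized (time, angle) coordinates
    i0, i1 = runs[0]
    peak = i0 + int(np.argmax(np.abs(x[i0:i1])))
    if peak == 0:
        return trace.start_time
    seg_t = np.arange(peak + 1) / peak
    a = np.abs(x[: peak + 1])
    rng_a = a.max() - a.min()
    an = (a - a.min()) / rng_a if rng_a > 0 else np.zeros_like(a)
    chord = np.array([seg_t[-1] - seg_t[0], an[-1] - an[0]])
    norm = np.hypot(*chord)
    if norm == 0:
        dist = np.abs(an - an[0])
    else:
        dist = np.abs(chord[0] * (an - an[0]) - chord[1] * (seg_t - seg_t[0])) / norm
    best = int(np.argmax(dist))  # argmax returns the earliest maximizer
    if dist[best] < min_prominence:
        log.info("chord-distance prominence %.3g below %.3g", dist[best], min_prominence)
        return None
    return trace.start_time + best / trace.fs


def quantize_wheel(
    trace: WheelTrace, step_fraction: float = 0.125
) -> tuple[WheelTrace, dict[str, float]]:
    """Snap the wheel signal to levels spaced ``step_fraction`` of its range.

    Levels span [min, max] of the trace. Returns the quantized trace plus a
    QC dict with the relative area-under-the-curve discrepancy (percent) and
    the Pearson correlation between original and quantized signals -- the
    published fidelity checks (< 5% and > 99%).
    """
    if not 0 < step_fraction <= 1:
        raise InvalidParameterError("step_fraction must be in (0, 1]")
    x = trace.samples
    mn, mx = x.min(), x.max()
    if mx == mn:
        raise DegenerateInputError("constant trace cannot be quantized")
    inv = 1.0 / step_fraction
    if abs(inv - round(inv)) < 1e-9:
        levels = np.linspace(mn, mx, int(round(inv)) + 1)
    else:
        levels = np.arange(mn, mx + 1e-12 * (mx - mn), step_fraction * (mx - mn))
    step = step_fraction * (mx - mn)
    idx = np.clip(np.round((x - mn) / step).astype(int), 0, levels.size - 1)
    q = levels[idx]

    dt = 1.0 / trace.fs
    # rectified area so left and right excursions cannot cancel
    auc_orig = np.trapezoid(np.abs(x), dx=dt)
    auc_quant = np.trapezoid(np.abs(q), dx=dt)
    auc_diff = np.abs(auc_orig - auc_quant) / np.abs(auc_orig) * 100.0 if auc_orig else np.inf
    corr = float(np.corrcoef(x, q)[0, 1])
    return (
        WheelTrace(q, fs=trace.fs, start_time=trace.start_time),
        {"auc_diff_pct": float(auc_diff), "corr": corr, "levels": levels},
    )


def binarize(
    qtrace: WheelTrace, min_gap: float = 1.0, min_duration: float = 0.25
) -> np.ndarray:
    """Boolean steering indicator from a quantized trace.

    Samples off the level nearest zero (the rest-position level) are 1.
    The raw indicator is then clustered: zero gaps shorter than ``min_gap``
    seconds are merged into the surrounding excursion and one-runs shorter
    than ``min_duration`` seconds are dropped, removing chatter where noise
    straddles a level boundary.
    """
    vals = np.unique(qtrace.samples)
    zero_level = vals[np.argmin(np.abs(vals))]
    b = ~np.isclose(qtrace.samples, zero_level)
    n_gap = int(round(min_gap * qtrace.fs))
    for i0, i1 in _suprathreshold_runs(~b):
        if i1 - i0 < n_gap and i0 > 0 and i1 < b.size:
            b[i0:i1] = True
    n_dur = int(round(min_duration * qtrace.fs))
    for i0, i1 in _suprathreshold_runs(b):
        if i1 - i0 < n_dur:
            b[i0:i1] = False
    return b


def binarize_transitions(qtrace: WheelTrace, direction_window: float = 0.5) -> EventTable:
    """Onsets at every 0 -> 1 transition of the binarized quantized trace.

    The steering direction is the sign of the mean wheel angle over the
    ``direction_window`` seconds following the transition (positive angle =
    left under the package convention).
    """
    b = binarize(qtrace)
    trans = np.flatnonzero(~b[:-1] & b[1:]) + 1
    onsets, labels = [], []
    n_win = max(int(round(direction_window * qtrace.fs)), 1)
    for i in trans:
        onsets.append(qtrace.start_time + i / qtrace.fs)
        labels.append("left" if qtrace.samples[i : i + n_win].mean() > 0 else "right")
    return EventTable(np.array(onsets), np.array(labels, object), np.arange(len(onsets)))


def segment_nonsteering(
    qtrace: WheelTrace,
    window: float = 4.0,
    hop: float = 1.0,
    guard: float = 0.0,
) -> EventTable:
    """Overlapping pseudo-event centers inside maximal non-steering runs.

    Centers are placed every ``hop`` seconds such that the full
    ``[-window/2, window/2]`` epoch plus ``guard`` stays within the all-zero
    run of the binarized trace. May return an empty table.
    """
    b = binarize(qtrace)
    runs = _suprathreshold_runs(~b)
    half = window / 2.0 + guard
    centers = []
    for i0, i1 in runs:
        run_start = qtrace.start_time + i0 / qtrace.fs
        run_end = qtrace.start_time + i1 / qtrace.fs
        c = run_start + half
        while c <= run_end - half + 1e-9:
            centers.append(c)
            c += hop
    centers = np.array(centers)
    return EventTable(
        centers, np.array(["nonsteer"] * centers.size, object), np.arange(centers.size)
    )


def epoch(
    signal: np.ndarray,
    fs: float,
    events: EventTable,
    window: tuple[float, float],
    start_time: float = 0.0,
    ch_names: list[str] | None = None,
) -> EpochSet:
    """Cut ``signal`` (channels x samples) into half-open [t_min, t_max) trials.

    Events whose window falls outside the recording are dropped with a
    logged reason; trial order follows event order.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    t_min, t_max = window
    n_win = int(round((t_max - t_min) * fs))
    chunks, labels = [], []
    for onset, label, tid in zip(events.onsets, events.labels, events.trial_ids):
        i0 = int(round((onset + t_min - start_time) * fs))
        if i0 < 0 or i0 + n_win > signal.shape[1]:
            log.warning("trial %d at %.3f s dropped: window outside recording", tid, onset)
            continue
        chunks.append(signal[:, i0 : i0 + n_win])
        labels.append(label)
    values = (
        np.stack(chunks) if chunks else np.empty((0, signal.shape[0], n_win))
    )
    return EpochSet(values, fs, window, ch_names or [], np.asarray(labels, object))
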