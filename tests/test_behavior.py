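"""Onset detection, quantization, segmentation and epoching contracts."""

import numpy as np
import pytest

from steercouple import EventTable, WheelTrace
from steercouple.behavior import (
    binarize_transitions,
    detect_onset_chord,
    epoch,
    quantize_wheel,
    segment_nonsteering,
)
from steercouple.containers import DegenerateInputError


def _chord_scan_oracle(x: np.ndarray, peak: int) -> int:
    """Exhaustive per-sample perpendicular-distance scan up to ``peak``."""
    a = np.abs(x[: peak + 1])
    tn = np.arange(peak + 1) / peak
    an = (a - a.min()) / (a.max() - a.min())
    p0 = np.array([0.0, an[0]])
    p1 = np.array([1.0, an[-1]])
    chord = p1 - p0
    best, best_d = 0, -1.0
    for i in range(peak + 1):
        d = abs(chord[0] * (an[i] - p0[1]) - chord[1] * (tn[i] - p0[0]))
        if d > best_d + 1e-15:
            best, best_d = i, d
    return best


class TestChordOnset:
    def test_flat_trace_returns_none(self):
        assert detect_onset_chord(WheelTrace(np.zeros(1000), 500)) is None

    def test_flat_then_ramp_breakpoint(self):
        """For a flat-zero head followed by a linear rise, the maximizer of
        the chord distance is the breakpoint where the movement starts
        (verified against an exhaustive per-sample scan)."""
        fs = 500.0
        x = np.concatenate([np.zeros(500), np.linspace(0, 90, 500)])
        onset = detect_onset_chord(WheelTrace(x, fs))
        peak = int(np.argmax(np.abs(x)))
        oracle = _chord_scan_oracle(x, peak)
        assert onset == pytest.approx(oracle / fs)
        assert abs(onset - 500 / fs) <= 2 / fs

    def test_default_threshold_is_two_degrees(self):
        x = np.concatenate([np.zeros(500), np.full(500, 1.5)])
        assert detect_onset_chord(WheelTrace(x, 500.0)) is None  # never above 2 deg
        x2 = np.concatenate([np.zeros(500), np.linspace(0, 2.5, 500)])
        assert detect_onset_chord(WheelTrace(x2, 500.0)) is not None

    def test_sign_flip_invariance(self, rng):
        x = np.concatenate([np.zeros(300), np.linspace(0, 80, 400), np.full(300, 80.0)])
        x = x + rng.normal(0, 0.3, x.size)
        t1 = detect_onset_chord(WheelTrace(x, 500.0))
        t2 = detect_onset_chord(WheelTrace(-x, 500.0))
        assert t1 == t2

    def test_ambiguous_trial_discarded(self):
        bump = np.concatenate([np.zeros(100), np.full(150, 10.0), np.zeros(400)])
        x = np.concatenate([bump, np.linspace(0, 90, 350)])
        assert detect_onset_chord(WheelTrace(x, 500.0)) is None
        assert detect_onset_chord(WheelTrace(x, 500.0), ambiguous="first") is not None


class TestQuantizer:
    def test_linear_ramp_staircase_correlation(self):
        """Quantizing a pure ramp yields the analytic staircase; the
        correlation matches the closed-form value on the staircase."""
        fs = 500.0
        n = 4000
        x = np.linspace(0.0, 90.0, n)
        q, qc = quantize_wheel(WheelTrace(x, fs), 0.125)
        levels = np.linspace(0, 90, 9)
        assert np.all(np.isin(np.round(q.samples, 9), np.round(levels, 9)))
        # closed form: corr(x, round(x)) for uniform x over the levels
        expected = np.corrcoef(x, levels[np.clip(np.round(x / 11.25), 0, 8).astype(int)])[0, 1]
        assert qc["corr"] == pytest.approx(expected, abs=1e-12)

    def test_vanishing_step_is_identity(self):
        x = np.sin(np.linspace(0, 3, 1000)) * 50
        q, qc = quantize_wheel(WheelTrace(x, 500.0), 1e-6)
        np.testing.assert_allclose(q.samples, x, atol=1e-3)
        assert qc["auc_diff_pct"] < 1e-3
        assert qc["corr"] > 1 - 1e-9

    def test_idempotence(self):
        x = np.sin(np.linspace(0, 3, 1000)) * 50
        q1, _ = quantize_wheel(WheelTrace(x, 500.0), 0.125)
        q2, qc2 = quantize_wheel(q1, 0.125)
        np.testing.assert_allclose(q2.samples, q1.samples, atol=1e-9)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            quantize_wheel(WheelTrace(np.full(100, 5.0), 500.0))


class TestBinarize:
    def test_all_zero_gives_empty_table(self):
        x = np.zeros(5000)
        x[0] = 1e-9  # avoid the degenerate constant trace
        q, _ = quantize_wheel(WheelTrace(x, 500.0), 0.125)
        assert len(binarize_transitions(q)) == 0

    def test_single_excursion_onset_matches_scan_oracle(self):
        fs = 500.0
        x = np.concatenate([np.zeros(1000), np.linspace(0, 90, 250),
                            np.full(500, 90.0), np.linspace(90, 0, 250), np.zeros(1000)])
        q, _ = quantize_wheel(WheelTrace(x, fs), 0.125)
        ev = binarize_transitions(q)
        assert len(ev) == 1
        # oracle: first sample whose quantized value leaves the zero level
        nz = np.flatnonzero(~np.isclose(q.samples, q.samples[0]))
        assert ev.onsets[0] == pytest.approx(nz[0] / fs)
        assert ev.labels[0] == "left"

    def test_k_excursions_k_onsets(self, small_session):
        q, _ = quantize_wheel(small_session.wheel, 0.125)
        ev = binarize_transitions(q)
        assert len(ev) == len(small_session.truth)
        # directions agree with ground truth in onset order
        assert list(ev.labels) == list(small_session.truth.directions)


class TestNonsteering:
    def test_center_count_on_all_zero_trace(self):
        x = np.zeros(5000)  # 10 s at 500 Hz
        x[0] = 1e-9
        q, _ = quantize_wheel(WheelTrace(x, 500.0), 0.125)
        ev = segment_nonsteering(q, window=4.0, hop=1.0, guard=0.0)
        assert len(ev) == 7  # floor((10 - 4) / 1) + 1
        np.testing.assert_allclose(ev.onsets, np.arange(2.0, 9.0))

    def test_no_room_gives_empty(self):
        x = np.zeros(1500)
        x[0] = 1e-9
        q, _ = quantize_wheel(WheelTrace(x, 500.0), 0.125)
        assert len(segment_nonsteering(q, window=4.0, hop=1.0, guard=0.0)) == 0

    def test_hop_equal_window_tiles_without_overlap(self):
        x = np.zeros(8000)  # 16 s
        x[0] = 1e-9
        q, _ = quantize_wheel(WheelTrace(x, 500.0), 0.125)
        ev = segment_nonsteering(q, window=4.0, hop=4.0, guard=0.0)
        starts = ev.onsets - 2.0
        assert np.all(np.diff(starts) >= 4.0 - 1e-9)

    def test_nonsteer_segments_avoid_excursions(self, small_session):
        q, _ = quantize_wheel(small_session.wheel, 0.125)
        ev = segment_nonsteering(q, window=4.0, hop=1.0, guard=0.2)
        exc = (small_session.spec.rise + small_session.spec.plateau
               + small_session.spec.fall)
        for c in ev.onsets:
            for onset in small_session.truth.onsets:
                assert c + 2.0 <= onset or c - 2.0 >= onset + exc


class TestEpoch:
    def test_sample_count_half_open(self):
        sig = np.zeros((2, 5000))
        ev = EventTable([5.0], ["left"], [0])
        ep = epoch(sig, 500.0, ev, (-2.5, 2.5))
        assert ep.values.shape == (1, 2, 2500)

    def test_empty_events_empty_epochs(self):
        ep = epoch(np.zeros((1, 1000)), 500.0, EventTable.empty(), (-1.0, 1.0))
        assert ep.n_trials == 0

    def test_out_of_bounds_event_dropped(self, caplog):
        sig = np.zeros((1, 1000))
        ev = EventTable([0.0, 1.0], ["left", "right"], [0, 1])
        with caplog.at_level("WARNING"):
            ep = epoch(sig, 500.0, ev, (-0.5, 0.5))
        assert ep.n_trials == 1
        assert list(ep.event_labels) == ["right"]
        assert "dropped" in caplog.text


def test_onset_algorithms_recover_ground_truth(small_session):
    """Both onset routes land close to the generator's ramp start: the
    chord route within the +/-40 ms recovery tolerance, the coarser
    quantize/binarize route within its half-level crossing delay."""
    s = small_session
    q, _ = quantize_wheel(s.wheel, 0.125)
    coarse = binarize_transitions(q)
    for onset in coarse.onsets:
        truth = s.truth.onsets[np.argmin(np.abs(s.truth.onsets - onset))]
        assert 0.0 <= onset - truth < 0.2
    n_win = int(4.0 * s.fs)
    refined = []
    for onset in coarse.onsets:
        i0 = int(round((onset - 2.0) * s.fs))
        tr = WheelTrace(s.wheel.samples[i0 : i0 + n_win], s.fs, start_time=i0 / s.fs)
        t = detect_onset_chord(tr)
        if t is not None:
            refined.append(t)
    assert len(refined) >= 0.8 * len(s.truth)
    errs = [
        abs(t - s.truth.onsets[np.argmin(np.abs(s.truth.onsets - t))]) for t in refined
    ]
    assert np.max(errs) <= 0.040
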