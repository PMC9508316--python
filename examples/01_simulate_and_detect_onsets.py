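"""Simulate a steering session and recover the onsets from the wheel angle.

Generates a short synthetic session (wheel + EEG + EMG), quantizes and
binarizes the continuous wheel signal for coarse onsets, refines each one
with the chord-distance method, and compares against ground truth.
"""

import numpy as np

from steercouple import PipelineConfig, SessionSpec, gen_session
from steercouple.behavior import quantize_wheel
from steercouple.pipeline import detect_steering_events

session = gen_session(SessionSpec(n_trials_left=10, n_trials_right=10, seed=3))
print(f"session: {session.duration:.0f} s, {len(session.truth)} steering trials")

_, qc = quantize_wheel(session.wheel, step_fraction=0.125)
print(
    f"quantizer QC: correlation {qc['corr'] * 100:.2f}% "
    f"(must stay > 99%), AUC discrepancy {qc['auc_diff_pct']:.2f}% (< 5%)"
)

events, info = detect_steering_events(session.wheel, PipelineConfig())
errors = []
for onset, label in zip(events.onsets, events.labels):
    j = int(np.argmin(np.abs(session.truth.onsets - onset)))
    errors.append((onset - session.truth.onsets[j]) * 1000)
    assert label == session.truth.directions[j]
print(
    f"detected {len(events)} onsets ({info['n_discarded']} discarded as ambiguous); "
    f"error vs ground truth: mean {np.mean(errors):.1f} ms, "
    f"max {np.max(np.abs(errors)):.1f} ms"
)
print("every detected onset lands within a few tens of ms of the true ramp start")
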