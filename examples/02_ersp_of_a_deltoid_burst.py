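"""Event-related spectral perturbation of a deltoid EMG burst.

Cuts EMG trials around the steering onsets and computes the Morlet ERSP on
the published EMG grid (2-200 Hz, 198 steps, 3-60 cycles, 10 ms hop) with
the single-trial [-2, 2] s divisive baseline. The contralateral deltoid
shows a broadband power increase starting just before the onset.
"""

from steercouple import PipelineConfig, SessionSpec, gen_session
from steercouple.behavior import epoch
from steercouple.pipeline import detect_steering_events
from steercouple.tfr import TFGrid, baseline_db, morlet_power, panel_window

session = gen_session(SessionSpec(n_trials_left=12, n_trials_right=12, seed=5))
events, _ = detect_steering_events(session.wheel, PipelineConfig())

epochs = epoch(
    session.emg, session.fs, events, (-2.5, 2.5), ch_names=session.emg_ch_names
)
left = epochs.select_label("left")
power = morlet_power(left, TFGrid.emg_preset(), channel="delt_r")
ersp = baseline_db(power, (-2.0, 2.0))
panel = panel_window(ersp, time_range=(-1.0, 2.0))
print(f"EMG ERSP panel: {panel.values.shape} (frequencies x 10 ms columns)")

pre = panel.values[:, panel.times < -0.5].mean()
burst = panel.values[:, (panel.times >= 0.0) & (panel.times < 1.0)].mean()
print(f"mean dB before the burst window: {pre:+.2f} dB")
print(f"mean dB during the movement:     {burst:+.2f} dB")
print(
    "the right (contralateral) deltoid gains broadband power during left "
    "steering; the panel is the 198 x 300 input to the coupling stage"
)
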