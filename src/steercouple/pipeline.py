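"""End-to-end orchestration: simulate -> onsets -> preprocess -> ICA ->
ERSP -> mask -> coupling -> statistics.

The pipeline runs a cohort of synthetic subjects (or data loaded from
disk via :mod:`steercouple.io`) through every stage and emits a
machine-readable report: event counts and discards, the chosen cluster
count and its stability, the reactive-cluster permutation p, the coupling
contrasts, Z scores against the half-split and shuffle nulls, and the
earliness of the coupling statistic relative to the EMG-only statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import behavior, coupling, ica_cluster, preprocess, stats, synth, tfr
from .config import PipelineConfig
from .containers import EventTable, WheelTrace
from .coupling import Mask
from .synth import Session

log = logging.getLogger(__name__)


def detect_steering_events(
    wheel: WheelTrace, cfg: PipelineConfig
) -> tuple[EventTable, dict]:
    """Quantize/binarize the continuous wheel signal for coarse onsets and
    directions, then refine each onset with the chord-distance method on a
    [-2, 2] s trial window. Trials the chord method discards are dropped."""
    qtrace, qc = behavior.quantize_wheel(wheel, cfg.step_fraction)
    coarse = behavior.binarize_transitions(qtrace, cfg.direction_window)
    onsets, labels = [], []
    n_discarded = 0
    n_win = int(round(4.0 * wheel.fs))
    for onset, label in zip(coarse.onsets, coarse.labels):
        i0 = int(round((onset - 2.0 - wheel.start_time) * wheel.fs))
        if i0 < 0 or i0 + n_win > wheel.samples.size:
            n_discarded += 1
            continue
        trial = WheelTrace(
            wheel.samples[i0 : i0 + n_win], wheel.fs, start_time=wheel.start_time + i0 / wheel.fs
        )
        refined = behavior.detect_onset_chord(
            trial, cfg.threshold_deg, cfg.min_prominence
        )
        if refined is None:
            n_discarded += 1
            continue
        onsets.append(refined)
        labels.append(label)
    order = np.argsort(onsets, kind="stable")
    events = EventTable(
        np.asarray(onsets)[order],
        np.asarray(labels, object)[order],
        np.arange(len(onsets)),
    )
    info = {
        "n_coarse": len(coarse),
        "n_discarded": n_discarded,
        "quantizer_qc": {k: qc[k] for k in ("auc_diff_pct", "corr")},
    }
    return events, info


@dataclass
class SubjectResult:
    """Everything the group stage needs from one subject."""

    events: EventTable
    event_info: dict
    nonsteer_events: EventTable
    n_trials_rejected: int
    scalp_maps: np.ndarray  # kept ICs x channels
    ic_ersp: dict  # condition -> (kept ICs, freqs, times) dB
    ersp_freqs: np.ndarray = field(default=None)
    ersp_times: np.ndarray = field(default=None)
    emg_trial_db: dict = field(default_factory=dict)  # muscle -> cond -> trials x F x T
    nonsteer_trial_db: dict = field(default_factory=dict)  # muscle -> trials x F x T
    emg_freqs: np.ndarray = field(default=None)
    emg_times: np.ndarray = field(default=None)
    truth_onsets: np.ndarray | None = None


def analyze_subject(session: Session, cfg: PipelineConfig, seed: int = 0) -> SubjectResult:
    """Single-subject pass: onsets, epoching, cleaning, ICA, ERSPs."""
    events, event_info = detect_steering_events(session.wheel, cfg)
    if len(events) < 5:
        raise RuntimeError(
            f"too few steering events detected ({len(events)}); "
            "check the wheel signal and onset thresholds"
        )
    qtrace, _ = behavior.quantize_wheel(session.wheel, cfg.step_fraction)
    nonsteer = behavior.segment_nonsteering(
        qtrace, cfg.nonsteer_window, cfg.nonsteer_hop, cfg.nonsteer_guard
    )
    if len(nonsteer) > cfg.max_nonsteer_trials:
        keep = np.arange(cfg.max_nonsteer_trials)
        nonsteer = EventTable(
            nonsteer.onsets[keep], nonsteer.labels[keep], nonsteer.trial_ids[keep]
        )

    # EEG: line noise, epoch, re-reference, reject, ICA
    eeg = preprocess.suppress_line_noise(
        session.eeg, session.fs, cfg.line_fundamental, cfg.n_harmonics
    )
    eeg_epochs = behavior.epoch(
        eeg, session.fs, events, cfg.epoch_window, ch_names=session.eeg_ch_names
    )
    eeg_epochs = preprocess.common_average_reference(eeg_epochs)
    eeg_epochs, report = preprocess.reject_artifact_trials(
        eeg_epochs, cfg.trend_z, cfg.spectrum_z
    )
    decomp = ica_cluster.decompose(eeg_epochs, cfg.n_components, seed=seed)
    kept = ica_cluster.select_brain_ics(decomp)
    if not kept:
        log.warning("subject contributes no brain-like components")

    eeg_grid = tfr.TFGrid.eeg_preset()
    ic_ersp: dict[str, list] = {"left": [], "right": []}
    freqs = times = None
    for k in kept:
        power = tfr.morlet_power(decomp.activations, eeg_grid, channel=k)
        for cond in ("left", "right"):
            rows = np.flatnonzero(decomp.activations.event_labels == cond)
            sub = tfr.TFPanel(
                power.values[rows], power.freqs, power.times,
                units="power", edge_mask=power.edge_mask,
            )
            panel = tfr.baseline_db(sub, cfg.eeg_baseline)
            ic_ersp[cond].append(panel.values)
            freqs, times = panel.freqs, panel.times
    ic_ersp_arr = {
        cond: (np.stack(v) if v else np.empty((0, eeg_grid.freqs.size, 0)))
        for cond, v in ic_ersp.items()
    }

    # EMG: line noise, epoch steering and non-steering trials, per-trial ERSP
    emg = preprocess.suppress_line_noise(
        session.emg, session.fs, cfg.line_fundamental, cfg.n_harmonics
    )
    emg_grid = tfr.TFGrid.emg_preset()
    steer_epochs = behavior.epoch(
        emg, session.fs, events, cfg.epoch_window, ch_names=session.emg_ch_names
    )
    nonsteer_epochs = behavior.epoch(
        emg, session.fs, nonsteer, cfg.epoch_window, ch_names=session.emg_ch_names
    )
    emg_trial_db: dict = {}
    nonsteer_trial_db: dict = {}
    emg_freqs = emg_times = None
    for muscle in cfg.muscles:
        power = tfr.morlet_power(steer_epochs, emg_grid, channel=muscle)
        db = tfr.baseline_db(power, cfg.emg_baseline, keep_trials=True)
        win = tfr.panel_window(db, time_range=cfg.emg_time)
        emg_trial_db[muscle] = {
            cond: win.values[steer_epochs.event_labels == cond]
            for cond in ("left", "right")
        }
        emg_freqs, emg_times = win.freqs, win.times
        if nonsteer_epochs.n_trials:
            npower = tfr.morlet_power(nonsteer_epochs, emg_grid, channel=muscle)
            ndb = tfr.baseline_db(npower, cfg.emg_baseline, keep_trials=True)
            nonsteer_trial_db[muscle] = tfr.panel_window(
                ndb, time_range=cfg.emg_time
            ).values

    return SubjectResult(
        events=events,
        event_info=event_info,
        nonsteer_events=nonsteer,
        n_trials_rejected=report.n_rejected,
        scalp_maps=decomp.scalp_maps()[kept] if kept else np.empty((0, session.eeg.shape[0])),
        ic_ersp=ic_ersp_arr,
        ersp_freqs=freqs,
        ersp_times=times,
        emg_trial_db=emg_trial_db,
        nonsteer_trial_db=nonsteer_trial_db,
        emg_freqs=emg_freqs,
        emg_times=emg_times,
        truth_onsets=session.truth.onsets,
    )


def group_analysis(subjects: list[SubjectResult], cfg: PipelineConfig) -> dict:
    """Cluster scalp maps across subjects, find the steering-reactive
    cluster, build masks, run the coupling and its statistics."""
    report: dict = {}

    owners, maps = [], []
    for s_idx, subj in enumerate(subjects):
        for row in range(subj.scalp_maps.shape[0]):
            owners.append((s_idx, row))
            maps.append(subj.scalp_maps[row])
    maps = np.asarray(maps)
    n_maps = maps.shape[0]
    report["n_maps"] = int(n_maps)
    if n_maps < 4:
        raise RuntimeError("too few brain-like components across subjects to cluster")

    # cap candidate k so clusters keep >= 3 members on average; subsampled
    # stability is not meaningful for near-singleton clusters
    k_max = min(cfg.k_max, n_maps // 3, n_maps - 1)
    k_max = max(k_max, cfg.k_min)
    k_star, curve = ica_cluster.stability_select_k(
        maps, range(cfg.k_min, k_max + 1), cfg.n_boot, cfg.subsample_fraction,
        seed=cfg.seed, threshold=cfg.stability_threshold,
    )
    assignment = ica_cluster.kmeans_scalp_maps(maps, k_star, seed=cfg.seed)
    report["k_star"] = int(k_star)
    report["stability"] = {int(k): float(v) for k, v in curve.items()}

    freqs = next(s.ersp_freqs for s in subjects if s.ersp_freqs is not None)
    times = next(s.ersp_times for s in subjects if s.ersp_times is not None)
    tcols = (times >= -2.0) & (times < 2.0)

    cluster_tests = {}
    for c in range(k_star):
        per_subj = {}
        for (s_idx, row), lab in zip(owners, assignment.labels):
            if lab == c:
                per_subj.setdefault(s_idx, []).append(row)
        if len(per_subj) < 2:
            continue
        panels = {
            cond: np.stack(
                [subjects[s].ic_ersp[cond][rows].mean(axis=0)[:, tcols]
                 for s, rows in sorted(per_subj.items())]
            )
            for cond in ("left", "right")
        }
        res = stats.perm_cluster_test(
            panels["left"], panels["right"], n_perm=cfg.n_perm, alpha=cfg.alpha,
            cluster_alpha=cfg.cluster_alpha, mass_exponent=cfg.mass_exponent,
            seed=cfg.seed,
        )
        cluster_tests[c] = (res, sorted(per_subj))
    if not cluster_tests:
        raise RuntimeError("no cluster had at least two contributing subjects")
    reactive = min(cluster_tests, key=lambda c: cluster_tests[c][0].min_p)
    reactive_res, reactive_subjects = cluster_tests[reactive]
    report["reactive_cluster"] = int(reactive)
    report["reactive_cluster_p"] = reactive_res.min_p
    report["reactive_cluster_significant"] = bool(reactive_res.min_p <= cfg.alpha)
    report["cluster_p"] = {int(c): t[0].min_p for c, t in cluster_tests.items()}
    report["n_subjects_in_cluster"] = len(reactive_subjects)

    # subject/condition masks from the reactive cluster's member ICs
    member_rows = {}
    for (s_idx, row), lab in zip(owners, assignment.labels):
        if lab == reactive:
            member_rows.setdefault(s_idx, []).append(row)
    masks: dict[str, dict[str, Mask]] = {}
    hop = float(times[1] - times[0])
    for s_idx in reactive_subjects:
        subj = subjects[s_idx]
        masks[str(s_idx)] = {}
        for cond in ("left", "right"):
            panel = tfr.TFPanel(
                subj.ic_ersp[cond][member_rows[s_idx]].mean(axis=0),
                freqs, times, units="dB",
            )
            masks[str(s_idx)][cond] = coupling.extract_mask(
                panel, cfg.mask_freq, cfg.mask_time
            )
    mask0 = next(iter(masks.values()))["left"]
    report["mask_shape"] = list(mask0.values.shape)

    emg_trials = {
        str(s_idx): subjects[s_idx].emg_trial_db for s_idx in reactive_subjects
    }
    panels = coupling.coupling_panels(masks, emg_trials, cfg.n_trim)
    subj_keys = sorted(panels)
    any_xc = next(iter(panels.values()))[(cfg.muscles[0], "left")]
    report["emg_panel_shape"] = [
        int(subjects[reactive_subjects[0]].emg_freqs.size),
        int(subjects[reactive_subjects[0]].emg_times.size),
    ]
    report["xcorr_shape_full"] = [
        int(any_xc.values.shape[0] + cfg.n_trim),
        int(any_xc.values.shape[1]),
    ]
    report["xcorr_shape_trimmed"] = list(any_xc.values.shape)

    def stacked(muscle: str, cond: str) -> np.ndarray:
        return np.stack([panels[s][(muscle, cond)].values for s in subj_keys])

    coupling_tests = {}
    for muscle in cfg.muscles:
        coupling_tests[f"{muscle}:left_vs_right"] = stats.perm_cluster_test(
            stacked(muscle, "left"), stacked(muscle, "right"),
            n_perm=cfg.n_perm, alpha=cfg.alpha, cluster_alpha=cfg.cluster_alpha,
            mass_exponent=cfg.mass_exponent, seed=cfg.seed,
        )
    if {"delt_l", "delt_r"} <= set(cfg.muscles):
        coupling_tests["contra_vs_ipsi:left_steer"] = stats.perm_cluster_test(
            stacked("delt_r", "left"), stacked("delt_l", "left"),
            n_perm=cfg.n_perm, alpha=cfg.alpha, cluster_alpha=cfg.cluster_alpha,
            mass_exponent=cfg.mass_exponent, seed=cfg.seed,
        )
        coupling_tests["contra_vs_ipsi:right_steer"] = stats.perm_cluster_test(
            stacked("delt_l", "right"), stacked("delt_r", "right"),
            n_perm=cfg.n_perm, alpha=cfg.alpha, cluster_alpha=cfg.cluster_alpha,
            mass_exponent=cfg.mass_exponent, seed=cfg.seed,
        )
        # the headline contrast pools both directions: per subject, mean
        # contralateral coupling vs mean ipsilateral coupling
        contra = 0.5 * (stacked("delt_r", "left") + stacked("delt_l", "right"))
        ipsi = 0.5 * (stacked("delt_l", "left") + stacked("delt_r", "right"))
        coupling_tests["contra_vs_ipsi:combined"] = stats.perm_cluster_test(
            contra, ipsi,
            n_perm=cfg.n_perm, alpha=cfg.alpha, cluster_alpha=cfg.cluster_alpha,
            mass_exponent=cfg.mass_exponent, seed=cfg.seed,
        )
    report["coupling_p"] = {k: v.min_p for k, v in coupling_tests.items()}

    # EMG-only contrast and earliness (coupling vs EMG, right deltoid)
    emg_tests = {}
    for muscle in cfg.muscles:
        a = np.stack(
            [subjects[int(s)].emg_trial_db[muscle]["left"].mean(axis=0) for s in subj_keys]
        )
        b = np.stack(
            [subjects[int(s)].emg_trial_db[muscle]["right"].mean(axis=0) for s in subj_keys]
        )
        emg_tests[muscle] = stats.perm_cluster_test(
            a, b, n_perm=cfg.n_perm, alpha=cfg.alpha,
            cluster_alpha=cfg.cluster_alpha, mass_exponent=cfg.mass_exponent,
            seed=cfg.seed,
        )
    report["emg_p"] = {k: v.min_p for k, v in emg_tests.items()}

    lead = None
    if "delt_r" in cfg.muscles:
        xc = panels[subj_keys[0]][("delt_r", "left")]
        xc_times = coupling.xcorr_times(xc, cfg.emg_time[0], hop)
        emg_times = subjects[int(subj_keys[0])].emg_times
        lead = stats.earliness(
            coupling_tests["delt_r:left_vs_right"].sig_mask,
            emg_tests["delt_r"].sig_mask,
            xc_times,
            emg_times,
        )
    report["earliness_s"] = lead

    # null constructions
    nonsteer = {
        str(s): subjects[int(s)].nonsteer_trial_db
        for s in subj_keys
        if subjects[int(s)].nonsteer_trial_db
    }
    observed = {
        muscle: float(np.mean(
            np.mean([panels[s][(muscle, "left")].values for s in subj_keys], axis=0)
            - np.mean([panels[s][(muscle, "right")].values for s in subj_keys], axis=0)
        ))
        for muscle in cfg.muscles
    }
    report["observed_mean_diff"] = observed
    if nonsteer:
        half = coupling.halfsplit_null(
            {s: nonsteer[s] for s in nonsteer}, masks, cfg.null_iter, seed=cfg.seed,
            n_trim=cfg.n_trim,
        )
        report["halfsplit_z"] = {}
        for muscle, ensemble in half.items():
            z, p = stats.z_against_null(observed[muscle], ensemble)
            report["halfsplit_z"][muscle] = {"z": z, "p": p}
    shuf = coupling.shuffle_null(
        emg_trials, masks, cfg.null_iter, seed=cfg.seed + 1, n_trim=cfg.n_trim
    )
    report["shuffle_z"] = {}
    for muscle, ensemble in shuf.items():
        z, p = stats.z_against_null(observed[muscle], ensemble)
        report["shuffle_z"][muscle] = {"z": z, "p": p}

    report["_objects"] = {
        "masks": masks,
        "panels": panels,
        "coupling_tests": coupling_tests,
        "emg_tests": emg_tests,
        "reactive_test": reactive_res,
        "reactive_test_freqs": freqs,
        "reactive_test_times": times[tcols],
        "assignment": assignment,
        "nonsteer_trials": nonsteer,
    }
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate ``cfg.n_subjects`` sessions and run the full analysis.

    Deterministic given ``cfg`` (including its seed). Returns the group
    report with a per-subject summary under ``"subjects"``; heavyweight
    intermediate objects are under ``"_objects"``.
    """
    subjects = []
    summaries = []
    for i in range(cfg.n_subjects):
        seed = int(
            np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)
        )
        spec_kwargs = {**cfg.session.__dict__, "seed": seed}
        session = synth.gen_session(synth.SessionSpec(**spec_kwargs))
        subj = analyze_subject(session, cfg, seed=seed)
        if len(subj.events) == 0:
            raise RuntimeError(f"subject {i}: no steering events detected")
        subjects.append(subj)
        summaries.append(
            {
                "n_events": len(subj.events),
                "n_left": int((subj.events.labels == "left").sum()),
                "n_right": int((subj.events.labels == "right").sum()),
                "n_nonsteer": len(subj.nonsteer_events),
                "n_discarded": subj.event_info["n_discarded"],
                "n_rejected": subj.n_trials_rejected,
                "quantizer_qc": subj.event_info["quantizer_qc"],
                "detected_onsets": subj.events.onsets.tolist(),
                "truth_onsets": subj.truth_onsets.tolist(),
                "n_maps": int(subj.scalp_maps.shape[0]),
            }
        )
    report = group_analysis(subjects, cfg)
    report["subjects"] = summaries
    return report
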