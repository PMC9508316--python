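"""Pipeline configuration with the published analysis constants as defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .containers import InvalidParameterError
from .synth import SessionSpec


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, validated at construction.

    Defaults follow the published analysis: +/-2 deg onset threshold,
    quantization step 0.125 of the wheel range, [-2.5, 2.5) s epochs,
    5 harmonics of 50 Hz, preset wavelet grids, mask over [8, 20] Hz x
    [-1.5, -1) s, EMG window [-1, 2) s, 12 trimmed rows, 1000 permutations,
    300 null iterations, alpha 0.05.
    """

    session: SessionSpec = field(default_factory=SessionSpec)
    n_subjects: int = 4
    seed: int = 0

    # behavior
    threshold_deg: float = 2.0
    min_prominence: float = 0.0
    step_fraction: float = 0.125
    direction_window: float = 0.5
    nonsteer_window: float = 4.0
    nonsteer_hop: float = 1.0
    nonsteer_guard: float = 1.7
    epoch_window: tuple[float, float] = (-2.5, 2.5)
    max_nonsteer_trials: int = 60

    # preprocessing
    line_fundamental: float = 50.0
    n_harmonics: int = 5
    trend_z: float = 5.0
    spectrum_z: float = 5.0

    # ICA + clustering
    n_components: int = 10
    k_min: int = 2
    k_max: int = 6
    n_boot: int = 10
    subsample_fraction: float = 0.8
    stability_threshold: float = 0.85

    # time-frequency
    eeg_baseline: tuple[float, float] = (-2.4, -1.6)  # onset-locked epochs
    eeg_baseline_cue: tuple[float, float] = (-0.5, -0.1)  # cue-locked epochs
    emg_baseline: tuple[float, float] = (-2.0, 2.0)

    # coupling
    mask_freq: tuple[float, float] = (8.0, 20.0)
    mask_time: tuple[float, float] = (-1.5, -1.0)
    emg_time: tuple[float, float] = (-1.0, 2.0)
    n_trim: int = 12
    muscles: tuple[str, ...] = ("delt_l", "delt_r")

    # statistics; n_perm may be "all" for exhaustive sign-flip enumeration
    n_perm: int | str = 1000
    null_iter: int = 300
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    mass_exponent: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.session, dict):
            self.session = SessionSpec(**self.session)
        for name in ("epoch_window", "eeg_baseline", "eeg_baseline_cue",
                     "emg_baseline", "mask_freq", "mask_time", "emg_time"):
            setattr(self, name, tuple(getattr(self, name)))
        self.muscles = tuple(self.muscles)
        if not 0 < self.alpha < 1 or not 0 < self.cluster_alpha < 1:
            raise InvalidParameterError("alpha values must lie in (0, 1)")
        if self.n_perm != "all" and (not isinstance(self.n_perm, int) or self.n_perm < 1):
            raise InvalidParameterError('n_perm must be a positive integer or "all"')
        if self.null_iter < 1:
            raise InvalidParameterError("null_iter must be positive")
        if not 0 < self.step_fraction <= 1:
            raise InvalidParameterError("step_fraction must be in (0, 1]")
        if self.threshold_deg <= 0:
            raise InvalidParameterError("threshold_deg must be positive")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise InvalidParameterError("need 2 <= k_min <= k_max")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)
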