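"""Shared in-memory containers for wheel, event and epoch data.

Angle sign convention: left steering is a positive wheel angle, right
steering negative. Both the generator and the direction labeller import
:data:`DIRECTION_SIGN` so the convention lives in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIRECTION_SIGN = {"left": 1.0, "right": -1.0}
EVENT_LABELS = ("left", "right", "nonsteer")


class InvalidParameterError(ValueError):
    """A parameter violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the operation."""


@dataclass
class WheelTrace:
    """Sampled steering-wheel angle in degrees."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise InvalidParameterError("WheelTrace samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("WheelTrace samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EventTable:
    """Rows of (onset [s], label, trial_id) sorted by onset."""

    onsets: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if not (self.onsets.size == self.labels.size == self.trial_ids.size):
            raise InvalidParameterError("EventTable columns must have equal length")
        bad = set(self.labels) - set(EVENT_LABELS)
        if bad:
            raise InvalidParameterError(f"unknown event labels: {sorted(bad)}")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            raise InvalidParameterError("event onsets must be sorted ascending")

    def __len__(self) -> int:
        return self.onsets.size

    def select(self, label: str) -> "EventTable":
        m = self.labels == label
        return EventTable(self.onsets[m], self.labels[m], self.trial_ids[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "label": self.labels, "trial_id": self.trial_ids}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["onset_s"].to_numpy(float),
            df["label"].to_numpy(object),
            df["trial_id"].to_numpy(int),
        )

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(np.empty(0), np.empty(0, object), np.empty(0, int))


@dataclass
class EpochSet:
    """Trials x channels x samples cut around events.

    The time window is half-open, ``[t_min, t_max)``, so the sample count is
    exactly ``round((t_max - t_min) * fs)``.
    """

    values: np.ndarray
    fs: float
    window: tuple[float, float]
    ch_names: list[str] = field(default_factory=list)
    event_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("EpochSet values must be trials x channels x samples")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        t_min, t_max = self.window
        n_expected = int(round((t_max - t_min) * self.fs))
        if self.values.shape[2] != n_expected:
            raise InvalidParameterError(
                f"sample count {self.values.shape[2]} does not match window "
                f"{self.window} at fs={self.fs} (expected {n_expected})"
            )
        if not self.ch_names:
            self.ch_names = [f"ch{i:03d}" for i in range(self.values.shape[1])]
        if self.event_labels is None:
            self.event_labels = np.asarray(["nonsteer"] * self.values.shape[0], object)
        else:
            self.event_labels = np.asarray(self.event_labels, dtype=object)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> int:
        return self.ch_names.index(name)

    def pick(self, trials: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.values[trials],
            self.fs,
            self.window,
            list(self.ch_names),
            self.event_labels[trials],
        )

    def select_label(self, label: str) -> "EpochSet":
        return self.pick(np.flatnonzero(self.event_labels == label))
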