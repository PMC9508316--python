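"""File formats: EDF continuous signals, TSV event tables, HDF5 panels.

EDF is written by a small built-in 16-bit encoder (one-second records,
per-channel physical scaling) and read back through MNE. Event tables are
tab-separated with columns onset_s, label, trial_id. Derived arrays
(TFPanel, Mask, XCorrMatrix, StatResult) round-trip bit-exactly through
HDF5 with their grid metadata and a format version tag.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EVENT_LABELS, EventTable, InvalidParameterError
from .coupling import Mask, XCorrMatrix
from .stats import StatResult
from .tfr import TFPanel

log = logging.getLogger(__name__)

FORMAT_VERSION = "steercouple-panels-1"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    ch_names: list[str],
    physical_dim: str = "",
) -> None:
    """Write channels x samples to a 16-bit EDF file (1 s data records).

    Each channel is scaled to its own physical min/max; the trailing
    partial record is zero-padded and the true sample count is stored in
    the recording-id field so :func:`read_edf` can trim it back.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise InvalidParameterError("one channel name per row required")
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise InvalidParameterError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / spr))

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(f"Startdate 01-JAN-2000 n={n_samp}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (1 + n_ch)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in ch_names:
            fh.write(_pad(name, 16))
        for _ in ch_names:
            fh.write(_pad("", 80))
        for _ in ch_names:
            fh.write(_pad(physical_dim, 8))
        for v in pmin:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in pmax:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        fh.write(_pad(str(dmin), 8) * n_ch)
        fh.write(_pad(str(dmax), 8) * n_ch)
        for _ in ch_names:
            fh.write(_pad("", 80))
        fh.write(_pad(str(spr), 8) * n_ch)
        fh.write(_pad("", 32) * n_ch)

        # re-read the 8-char headers we just committed so the digital
        # scaling matches the (truncated) physical min/max exactly
        pmin_h = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
        pmax_h = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
        scale = (dmax - dmin) / (pmax_h - pmin_h)
        padded = np.zeros((n_ch, n_rec * spr))
        padded[:, :n_samp] = data
        dig = np.clip(
            np.round((padded - pmin_h[:, None]) * scale[:, None] + dmin), dmin, dmax
        ).astype("<i2")
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(
    path: str | Path,
    expected_channels: int | None = None,
    expected_fs: float | None = None,
) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file (via MNE) into (channels x samples, fs, names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    names = list(raw.ch_names)
    if expected_channels is not None and data.shape[0] != expected_channels:
        raise InvalidParameterError(
            f"expected {expected_channels} channels, file has {data.shape[0]}"
        )
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise InvalidParameterError(f"expected fs={expected_fs}, file has {fs}")
    # trim zero padding if the writer recorded the true sample count
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace")
    m = re.search(r"n=(\d+)", rec_id)
    if m:
        data = data[:, : int(m.group(1))]
    return data, fs, names


def write_events(path: str | Path, events: EventTable) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventTable:
    """Read a TSV event table; unsorted rows are sorted with a warning,
    unknown labels raise."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["label"]) - set(EVENT_LABELS)
    if bad:
        raise InvalidParameterError(f"unknown event labels in {path}: {sorted(bad)}")
    if not df["onset_s"].is_monotonic_increasing:
        log.warning("events in %s were not sorted by onset; sorting", path)
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return EventTable.from_frame(df)


# ---------------------------------------------------------------------------
# HDF5 panels


def _write_obj(grp: h5py.Group, obj) -> None:
    if isinstance(obj, TFPanel):
        grp.attrs["class"] = "TFPanel"
        grp.attrs["units"] = obj.units
        if obj.baseline_window is not None:
            grp.attrs["baseline_window"] = obj.baseline_window
        grp.create_dataset("values", data=obj.values)
        grp.create_dataset("freqs", data=obj.freqs)
        grp.create_dataset("times", data=obj.times)
        if obj.edge_mask is not None:
            grp.create_dataset("edge_mask", data=obj.edge_mask)
    elif isinstance(obj, Mask):
        grp.attrs["class"] = "Mask"
        grp.create_dataset("values", data=obj.values)
        grp.create_dataset("freqs", data=obj.freqs)
        grp.create_dataset("times", data=obj.times)
    elif isinstance(obj, XCorrMatrix):
        grp.attrs["class"] = "XCorrMatrix"
        for key, val in obj.provenance.items():
            grp.attrs[f"prov_{key}"] = val
        grp.create_dataset("values", data=obj.values)
        grp.create_dataset("row_lags", data=obj.row_lags)
        grp.create_dataset("col_lags", data=obj.col_lags)
    elif isinstance(obj, StatResult):
        grp.attrs["class"] = "StatResult"
        grp.attrs["alpha"] = obj.alpha
        grp.attrs["threshold"] = obj.threshold
        grp.attrs["n_permutations"] = obj.n_permutations
        if obj.seed is not None:
            grp.attrs["seed"] = obj.seed
        grp.create_dataset("t_map", data=obj.t_map)
        grp.create_dataset("cluster_labels", data=obj.cluster_labels)
        grp.create_dataset("cluster_masses", data=obj.cluster_masses)
        grp.create_dataset("cluster_p", data=obj.cluster_p)
        grp.create_dataset("sig_mask", data=obj.sig_mask)
    else:
        raise InvalidParameterError(f"cannot serialize {type(obj).__name__}")


def _read_obj(grp: h5py.Group):
    cls = grp.attrs.get("class")
    if cls is None:
        raise InvalidParameterError("missing class metadata in panel file")
    if cls == "TFPanel":
        bw = grp.attrs.get("baseline_window")
        return TFPanel(
            grp["values"][()],
            grp["freqs"][()],
            grp["times"][()],
            units=str(grp.attrs["units"]),
            baseline_window=None if bw is None else tuple(bw),
            edge_mask=grp["edge_mask"][()].astype(bool) if "edge_mask" in grp else None,
        )
    if cls == "Mask":
        return Mask(grp["values"][()], grp["freqs"][()], grp["times"][()])
    if cls == "XCorrMatrix":
        prov = {
            k[5:]: (v.item() if hasattr(v, "item") else v)
            for k, v in grp.attrs.items()
            if k.startswith("prov_")
        }
        return XCorrMatrix(
            grp["values"][()], grp["row_lags"][()], grp["col_lags"][()], provenance=prov
        )
    if cls == "StatResult":
        return StatResult(
            t_map=grp["t_map"][()],
            cluster_labels=grp["cluster_labels"][()],
            cluster_masses=grp["cluster_masses"][()],
            cluster_p=grp["cluster_p"][()],
            sig_mask=grp["sig_mask"][()].astype(bool),
            alpha=float(grp.attrs["alpha"]),
            threshold=float(grp.attrs["threshold"]),
            n_permutations=int(grp.attrs["n_permutations"]),
            seed=int(grp.attrs["seed"]) if "seed" in grp.attrs else None,
        )
    raise InvalidParameterError(f"unknown panel class {cls!r}")


def save_panels(path: str | Path, objects: dict[str, object]) -> None:
    """Save a named collection of panels/matrices/results to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = FORMAT_VERSION
        for name, obj in objects.items():
            _write_obj(fh.create_group(name), obj)


def load_panels(path: str | Path) -> dict[str, object]:
    """Load a panel collection; raises on a missing or foreign version tag."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format")
        if version != FORMAT_VERSION:
            raise InvalidParameterError(
                f"unsupported panel file version {version!r} (expected {FORMAT_VERSION})"
            )
        return {name: _read_obj(fh[name]) for name in fh}
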