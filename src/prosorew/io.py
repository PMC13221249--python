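"""Epoch I/O: the internal HDF5 dialect and external-format readers.

Internal layout (version 1.x)::

    /data            float32, (trial, channel, time), μV
    /times_ms        float64
    /channels        variable-length UTF-8 strings
    /positions       float64, (channel, 2)
    /conditions/<col>  one dataset per condition column
    attrs: format_version, participant_id, baseline_window (optional)

Readers reject files whose major format version they do not know.

External formats (read-only):

* ``edf+`` — continuous EDF+ with one annotation per feedback onset; trials
  are cut around each annotation using a caller-supplied epoch window and the
  annotation text is mapped to a design cell through ``event_map``.
* ``eeglab-set`` — epoched EEGLAB ``.set`` files; the per-epoch event type is
  mapped through ``event_map``.

``event_map`` maps event code/description -> ``(beneficiary, magnitude,
time)`` level triple; a code present in the file but absent from the map is
an error naming that code.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import CODES, LEVELS
from .epochs import CONDITION_COLUMNS, EpochSet, EpochsError
from . import layout as _layout

FORMAT_VERSION = "1.0"


def write_epochs(e: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` in the internal HDF5 dialect."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["participant_id"] = e.participant_id
        if e.baseline_window is not None:
            f.attrs["baseline_window"] = np.asarray(e.baseline_window, dtype=float)
        f.create_dataset("data", data=e.data.astype(np.float32))
        f.create_dataset("times_ms", data=e.times)
        f.create_dataset("channels", data=np.array(e.channels, dtype=object),
                         dtype=h5py.string_dtype())
        f.create_dataset("positions", data=e.positions)
        g = f.create_group("conditions")
        for col in e.conditions.columns:
            vals = e.conditions[col].to_numpy()
            if vals.dtype.kind in ("O", "U"):
                g.create_dataset(col, data=vals.astype(object),
                                 dtype=h5py.string_dtype())
            else:
                g.create_dataset(col, data=vals)


def _read_internal(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("format_version", ""))
        major = version.split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise EpochsError(
                f"unsupported epoch-file format version {version!r}")
        cond = {}
        for col in f["conditions"]:
            vals = f["conditions"][col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v
                                 for v in vals])
            cond[col] = vals
        bw = f.attrs.get("baseline_window")
        return EpochSet(
            data=f["data"][()].astype(float),
            times=f["times_ms"][()],
            channels=[c.decode() if isinstance(c, bytes) else c
                      for c in f["channels"][()]],
            positions=f["positions"][()],
            conditions=pd.DataFrame(cond),
            participant_id=str(f.attrs.get("participant_id", "p00")),
            baseline_window=tuple(bw) if bw is not None else None,
        )


def _conditions_from_codes(codes: list[str],
                           event_map: dict[str, tuple[str, str, str]]) -> pd.DataFrame:
    rows = []
    for code in codes:
        if code not in event_map:
            raise EpochsError(f"no condition mapping for event code {code!r}")
        b, m, t = event_map[code]
        for f_, lv in zip(("beneficiary", "magnitude", "time"), (b, m, t)):
            if lv not in LEVELS[f_]:
                raise EpochsError(f"unknown {f_} level {lv!r} for code {code!r}")
        rows.append({
            "beneficiary": b, "magnitude": m, "time": t,
            "beneficiary_coded": CODES["beneficiary"][b],
            "magnitude_coded": CODES["magnitude"][m],
            "time_coded": CODES["time"][t],
        })
    return pd.DataFrame(rows, columns=CONDITION_COLUMNS)


def _positions_for(channels: list[str]) -> np.ndarray:
    """Look up 2-D positions for known montage names; NaN for unknown."""
    pos = np.full((len(channels), 2), np.nan)
    all_names = list(_layout.CHANNELS_62)
    lookup = dict(zip(all_names, _layout.positions_2d(all_names)))
    for i, ch in enumerate(channels):
        if ch in lookup:
            pos[i] = lookup[ch]
    return pos


def _read_edfplus(path: str | Path,
                  event_map: dict[str, tuple[str, str, str]],
                  window: tuple[float, float]) -> EpochSet:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = raw.info["sfreq"]
    data = raw.get_data() * 1e6  # Volt -> μV
    ann = raw.annotations
    if len(ann) == 0:
        raise EpochsError("EDF+ file carries no annotations to epoch on")
    lo, hi = window
    n_lo = int(round(lo * sfreq / 1000.0))
    n_hi = int(round(hi * sfreq / 1000.0))
    times = np.arange(n_lo, n_hi + 1) / sfreq * 1000.0
    epochs, codes = [], []
    for onset, desc in zip(ann.onset, ann.description):
        s = int(round(onset * sfreq))
        if s + n_lo < 0 or s + n_hi >= data.shape[1]:
            raise EpochsError(
                f"epoch window {window} ms around annotation at {onset:.3f} s "
                "falls outside the recording")
        epochs.append(data[:, s + n_lo : s + n_hi + 1])
        codes.append(desc)
    conditions = _conditions_from_codes(codes, event_map)
    channels = list(raw.ch_names)
    return EpochSet(
        data=np.stack(epochs, axis=0),
        times=times,
        channels=channels,
        positions=_positions_for(channels),
        conditions=conditions,
        participant_id=Path(path).stem,
    )


def _read_eeglab_set(path: str | Path,
                     event_map: dict[str, tuple[str, str, str]]) -> EpochSet:
    import mne

    ep = mne.io.read_epochs_eeglab(path, verbose="error")
    data = ep.get_data(copy=True) * 1e6
    inv = {v: k for k, v in ep.event_id.items()}
    codes = [inv[int(code)] for code in ep.events[:, 2]]
    conditions = _conditions_from_codes(codes, event_map)
    channels = list(ep.ch_names)
    return EpochSet(
        data=data,
        times=ep.times * 1000.0,
        channels=channels,
        positions=_positions_for(channels),
        conditions=conditions,
        participant_id=Path(path).stem,
    )


def read_epochs(
    path: str | Path,
    format: str = "internal-hdf5",
    event_map: dict[str, tuple[str, str, str]] | None = None,
    window: tuple[float, float] | None = None,
) -> EpochSet:
    """Read epochs from ``path``.

    Parameters
    ----------
    format
        ``"internal-hdf5"``, ``"edf+"`` or ``"eeglab-set"``.
    event_map
        Required for external formats: event code -> (beneficiary,
        magnitude, time) level triple.
    window
        Required for ``"edf+"``: epoch window in ms around each annotation.
    """
    if format == "internal-hdf5":
        return _read_internal(path)
    if format == "edf+":
        if event_map is None:
            raise EpochsError("edf+ reading requires an event_map")
        if window is None:
            raise EpochsError("edf+ reading requires an epoch window")
        return _read_edfplus(path, event_map, window)
    if format == "eeglab-set":
        if event_map is None:
            raise EpochsError("eeglab-set reading requires an event_map")
        return _read_eeglab_set(path, event_map)
    raise EpochsError(f"unknown epoch format {format!r}")
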