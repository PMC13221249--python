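"""Single-trial epoch container, preprocessing, and artifact screening.

The :class:`EpochSet` is the package's canonical in-memory object: a
``(trial, channel, time)`` voltage array in microvolts, time-locked to
feedback onset, with an attached per-trial condition table (factor levels
plus their ±0.5 codes) and 2-D channel positions.

Preprocessing mirrors a conventional feedback ERP pipeline: zero-phase
Butterworth band-pass, re-reference to the averaged mastoids, prestimulus
baseline subtraction, and a four-rule automatic artifact screen
(sample-to-sample step, within-epoch range, flatline, slow drift).
All rule thresholds use strict inequalities, so a value exactly at
threshold does not fire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal
from scipy.ndimage import maximum_filter1d

from .design import FACTORS

CONDITION_COLUMNS = [
    "beneficiary", "magnitude", "time",
    "beneficiary_coded", "magnitude_coded", "time_coded",
]


class EpochsError(ValueError):
    """Raised on contract violations in epoch handling."""


@dataclass
class EpochSet:
    """Single-trial multichannel voltage epochs with condition metadata.

    Parameters
    ----------
    data
        Voltages, shape ``(n_trials, n_channels, n_times)``, microvolts.
    times
        Time axis in ms relative to feedback onset; strictly increasing
        with a uniform step.
    channels
        Ordered channel names (unique).
    positions
        2-D channel positions, shape ``(n_channels, 2)``.
    conditions
        Per-trial factor levels and coded values (one row per trial).
    participant_id
        Label of the participant the epochs belong to.
    baseline_window
        ``None`` if no baseline has been subtracted, else the ``(start_ms,
        end_ms)`` window that was used.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    positions: np.ndarray
    conditions: pd.DataFrame
    participant_id: str = "p00"
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.data.ndim != 3:
            raise EpochsError("data must be (trial, channel, time)")
        n_tr, n_ch, n_t = self.data.shape
        if self.times.shape != (n_t,):
            raise EpochsError("times length does not match data")
        dt = np.diff(self.times)
        if n_t > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise EpochsError("times must be strictly increasing and uniform")
        if len(self.channels) != n_ch:
            raise EpochsError("channel list does not match data")
        if len(set(self.channels)) != n_ch:
            raise EpochsError("duplicate channel names")
        if self.positions.shape != (n_ch, 2):
            raise EpochsError("positions must be (n_channels, 2)")
        if len(self.conditions) != n_tr:
            raise EpochsError("condition table row count does not match trials")
        for f in FACTORS:
            col = f"{f}_coded"
            if col in self.conditions:
                vals = set(np.unique(self.conditions[col]))
                if not vals <= {-0.5, 0.5}:
                    raise EpochsError(f"{col} must be coded ±0.5, got {vals}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / (self.times[1] - self.times[0])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise EpochsError(f"channel {name!r} not present") from None

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples inside ``window`` (endpoints inclusive,
        nearest sample at or inside each endpoint)."""
        lo, hi = window
        if lo > hi:
            raise EpochsError(f"window {window} is empty")
        mask = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not mask.any():
            raise EpochsError(f"window {window} contains no samples")
        return mask

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            channels=list(self.channels),
            positions=self.positions.copy(),
            conditions=self.conditions.copy(),
        )

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        return replace(
            self,
            data=self.data[idx],
            conditions=self.conditions.iloc[np.atleast_1d(idx)].reset_index(drop=True),
        )


@dataclass
class RejectionReport:
    """Outcome of the artifact screen: per-trial keep flags and fired rules."""

    keep: np.ndarray
    rules_fired: list[list[str]]
    all_rejected: bool = field(default=False)

    @property
    def retained_fraction(self) -> float:
        return float(np.mean(self.keep))


#: thresholds of the four automatic rejection rules
DEFAULT_REJECTION = {
    "step": 50.0,       # μV between consecutive samples
    "range": 200.0,     # μV peak-to-peak within an epoch
    "flatline": 0.5,    # μV max step within any 100-ms window
    "drift": 100.0,     # μV fitted slope magnitude over the epoch
}

FLATLINE_WINDOW_MS = 100.0


def _rule_step(data: np.ndarray, thr: float) -> np.ndarray:
    d = np.abs(np.diff(data, axis=2))
    return (d > thr).any(axis=(1, 2))


def _rule_range(data: np.ndarray, thr: float) -> np.ndarray:
    ptp = data.max(axis=2) - data.min(axis=2)
    return (ptp > thr).any(axis=1)


def _rule_flatline(data: np.ndarray, thr: float, sfreq: float) -> np.ndarray:
    # a 100-ms stretch on any channel where every consecutive step is < thr
    d = np.abs(np.diff(data, axis=2))
    w = max(int(round(FLATLINE_WINDOW_MS * sfreq / 1000.0)) - 1, 1)
    if d.shape[2] < w:
        return np.zeros(data.shape[0], dtype=bool)
    winmax = maximum_filter1d(d, size=w, axis=2, mode="nearest")
    # valid window centres only (avoid edge windows shorter than w)
    half = w // 2
    valid = winmax[:, :, half : d.shape[2] - (w - 1 - half)]
    return (valid < thr).any(axis=(1, 2))


def _rule_drift(data: np.ndarray, thr: float, times: np.ndarray) -> np.ndarray:
    t = (times - times.mean())
    denom = float((t ** 2).sum())
    slope_per_ms = np.tensordot(data, t, axes=([2], [0])) / denom
    drift = np.abs(slope_per_ms) * (times[-1] - times[0])  # μV over the epoch
    return (drift > thr).any(axis=1)


def reject_artifacts(
    e: EpochSet,
    rules: dict[str, float] | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials on which any enabled artifact rule fires on any channel.

    Parameters
    ----------
    e
        Input epochs.
    rules
        Mapping of rule name (subset of ``{"step", "range", "flatline",
        "drift"}``) to its threshold; defaults to the four conventional
        thresholds in :data:`DEFAULT_REJECTION`.

    Returns
    -------
    (clean_epochs, report)
        The retained trials and a :class:`RejectionReport`.  If every trial
        is rejected, a warning is raised and the report's ``all_rejected``
        flag is set; the returned :class:`EpochSet` is empty.
    """
    if rules is None:
        rules = dict(DEFAULT_REJECTION)
    unknown = set(rules) - set(DEFAULT_REJECTION)
    if unknown:
        raise EpochsError(f"unknown rejection rules: {sorted(unknown)}")
    for name, thr in rules.items():
        if thr <= 0:
            raise EpochsError(f"threshold for {name!r} must be positive")

    fired: dict[str, np.ndarray] = {}
    if "step" in rules:
        fired["step"] = _rule_step(e.data, rules["step"])
    if "range" in rules:
        fired["range"] = _rule_range(e.data, rules["range"])
    if "flatline" in rules:
        fired["flatline"] = _rule_flatline(e.data, rules["flatline"], e.sfreq)
    if "drift" in rules:
        fired["drift"] = _rule_drift(e.data, rules["drift"], e.times)

    n = e.n_trials
    reject = np.zeros(n, dtype=bool)
    for flags in fired.values():
        reject |= flags
    rules_fired = [
        [name for name, flags in fired.items() if flags[i]] for i in range(n)
    ]
    keep = ~reject
    report = RejectionReport(keep=keep, rules_fired=rules_fired)
    if n > 0 and not keep.any():
        report.all_rejected = True
        warnings.warn("all trials rejected by artifact screen", stacklevel=2)
    return e.select_trials(np.flatnonzero(keep)), report


def baseline_subtract(e: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window``.

    Raises if the epochs have already been baselined (double baselining
    silently shifts the zero level and is almost always a bug).
    """
    if e.baseline_window is not None:
        raise EpochsError(f"epochs already baselined over {e.baseline_window}")
    if window[0] < e.times[0] - 1e-9 or window[1] > e.times[-1] + 1e-9:
        raise EpochsError(f"baseline window {window} outside epoch "
                          f"({e.times[0]:.0f}..{e.times[-1]:.0f} ms)")
    mask = e.time_mask(window)
    out = e.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    out.baseline_window = (float(window[0]), float(window[1]))
    return out


def filter_bandpass(
    e: EpochSet, lo_hz: float = 0.1, hi_hz: float = 35.0, order: int = 2
) -> EpochSet:
    """Zero-phase Butterworth band-pass (forward-backward on each epoch).

    ``order`` is the order of the one-pass filter; the default 2 gives a
    12 dB/octave roll-off before the forward-backward application doubles
    the effective attenuation.  Epoch edges are handled by the odd-reflection
    padding built into ``sosfiltfilt``.
    """
    nyq = e.sfreq / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise EpochsError(
            f"invalid band {lo_hz}-{hi_hz} Hz for sampling rate {e.sfreq} Hz")
    sos = scipy.signal.butter(order, [lo_hz, hi_hz], btype="bandpass",
                              fs=e.sfreq, output="sos")
    out = e.copy()
    out.data = scipy.signal.sosfiltfilt(sos, out.data, axis=2)
    return out


def rereference_mastoids(e: EpochSet, left: str = "M1", right: str = "M2") -> EpochSet:
    """Re-reference every channel to the average of the two mastoids."""
    il, ir = e.channel_index(left), e.channel_index(right)
    out = e.copy()
    ref = 0.5 * (out.data[:, il, :] + out.data[:, ir, :])
    out.data = out.data - ref[:, None, :]
    return out
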