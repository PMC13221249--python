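"""Single-trial Morlet decomposition and welding-baseline normalization.

The wavelet bank spans 1–30 Hz in 30 logarithmically (geometrically) spaced
steps with cycle counts increasing geometrically from 3 to 10, paired
index-wise with the frequencies.  Wavelets are scaled so their frequency
response peaks at gain 2, which makes a unit-amplitude sinusoid at a bank
frequency yield unit peak power regardless of frequency — power is then
amplitude² on the ridge.

Normalization follows the "welding" scheme for single-trial power: for each
channel × frequency, the baseline-window samples of *all* trials are pooled
("welded") into a single long baseline, and every sample of every trial is
z-scored by that pooled mean and SD.  Pooling across trials avoids the bias
of per-trial baselines, whose handful of samples make noisy, heavy-tailed
divisors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet, EpochsError
from .erp import SingleTrialScores
import pandas as pd

from .epochs import CONDITION_COLUMNS


@dataclass
class WaveletBank:
    """Complex Morlet bank: geometric frequency and cycle ladders."""

    f_min: float = 1.0
    f_max: float = 30.0
    n_freqs: int = 30
    cycles_min: float = 3.0
    cycles_max: float = 10.0
    sampling_rate: float = 500.0

    frequencies: np.ndarray = field(init=False)
    cycles: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise EpochsError("need 0 < f_min < f_max")
        self.frequencies = np.geomspace(self.f_min, self.f_max, self.n_freqs)
        self.cycles = np.geomspace(self.cycles_min, self.cycles_max, self.n_freqs)

    def sigma_t(self, i: int) -> float:
        """Temporal SD (s) of wavelet ``i``: cycles / (2π f)."""
        return self.cycles[i] / (2.0 * np.pi * self.frequencies[i])

    def max_halfwidth_samples(self) -> int:
        """Half-length (samples) of the longest wavelet (±3.5 temporal SD)."""
        widths = [self.sigma_t(i) for i in range(self.n_freqs)]
        return int(np.ceil(3.5 * max(widths) * self.sampling_rate))


@dataclass
class TFRArray:
    """Trial × channel × frequency × time power with normalization state."""

    power: np.ndarray
    times: np.ndarray
    frequencies: np.ndarray
    channels: list[str]
    conditions: pd.DataFrame
    participant_id: str = "p00"
    normalization: str = "raw"                      # "raw" | "welded-z"
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.power.ndim != 4:
            raise EpochsError("power must be (trial, channel, freq, time)")
        if self.normalization == "raw" and (self.power < 0).any():
            raise EpochsError("raw power must be nonnegative")

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        mask = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not mask.any():
            raise EpochsError(f"window {window} contains no samples")
        return mask


def _morlet_kernel(freq: float, cycles: float, sfreq: float) -> np.ndarray:
    """Complex Morlet, scaled so its frequency response peaks at 2."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    env = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    w = env * np.exp(2j * np.pi * freq * t)
    # discrete response to exp(i2πft) is env.sum(); gain 2 recovers real
    # sinusoid amplitude in |conv| (the negative frequency is rejected)
    return 2.0 * w / env.sum()


def morlet_transform(
    e: EpochSet,
    bank: WaveletBank | None = None,
    channels: list[str] | None = None,
    crop: tuple[float, float] | None = None,
) -> TFRArray:
    """Single-trial power via FFT convolution with the Morlet bank.

    Epochs are reflection-padded by one half-wavelet length at the lowest
    frequency before convolution; the pad is discarded afterwards.

    Parameters
    ----------
    channels
        Optional channel subset (saves memory: the full 4-D array is
        ``trial × channel × frequency × time``).
    crop
        Optional output window in ms (applied after the transform).
    """
    if bank is None:
        bank = WaveletBank(sampling_rate=e.sfreq)
    if abs(bank.sampling_rate - e.sfreq) > 1e-6:
        bank = WaveletBank(bank.f_min, bank.f_max, bank.n_freqs,
                           bank.cycles_min, bank.cycles_max, e.sfreq)
    if channels is not None:
        idx = [e.channel_index(ch) for ch in channels]
        data = e.data[:, idx, :]
        ch_names = list(channels)
    else:
        data = e.data
        ch_names = list(e.channels)

    n_tr, n_ch, n_t = data.shape
    pad = bank.max_halfwidth_samples()
    if n_t < pad:
        need_ms = pad / e.sfreq * 1000.0
        raise EpochsError(
            f"epoch too short for the {bank.f_min:g} Hz wavelet: needs at "
            f"least {need_ms:.0f} ms of signal for reflection padding")

    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    n_p = padded.shape[2]
    n_fft = int(2 ** np.ceil(np.log2(n_p + 2 * pad + 1)))
    spec = np.fft.fft(padded, n=n_fft, axis=2)

    power = np.empty((n_tr, n_ch, bank.n_freqs, n_t))
    for i in range(bank.n_freqs):
        w = _morlet_kernel(bank.frequencies[i], bank.cycles[i], e.sfreq)
        wf = np.fft.fft(w, n=n_fft)
        conv = np.fft.ifft(spec * wf, axis=2)
        half = (len(w) - 1) // 2
        start = pad + half
        power[:, :, i, :] = np.abs(conv[:, :, start : start + n_t]) ** 2

    times = e.times.copy()
    if crop is not None:
        mask = (times >= crop[0] - 1e-9) & (times <= crop[1] + 1e-9)
        power = power[:, :, :, mask]
        times = times[mask]
    return TFRArray(
        power=power, times=times, frequencies=bank.frequencies.copy(),
        channels=ch_names, conditions=e.conditions.copy(),
        participant_id=e.participant_id,
    )


def weld_baseline(t: TFRArray, window: tuple[float, float] = (-500.0, -300.0)) -> TFRArray:
    """Normalize single-trial power against the trial-pooled baseline.

    Per channel × frequency, all baseline-window samples of all trials form
    one pooled vector with mean μ and SD σ; every sample of every trial
    becomes ``(p − μ)/σ``.  After normalization the pooled baseline samples
    have mean 0 and SD 1 exactly.
    """
    if t.normalization != "raw":
        raise EpochsError(f"power already normalized ({t.normalization})")
    mask = t.time_mask(window)
    base = t.power[:, :, :, mask]                       # tr × ch × f × bt
    nb = base.shape[0] * base.shape[3]
    pooled = base.transpose(1, 2, 0, 3).reshape(base.shape[1], base.shape[2], nb)
    mu = pooled.mean(axis=2)
    sd = pooled.std(axis=2)                             # population SD
    if (sd <= 0).any():
        raise EpochsError("degenerate welding baseline: zero variance in at "
                          "least one channel × frequency")
    z = (t.power - mu[None, :, :, None]) / sd[None, :, :, None]
    return TFRArray(
        power=z, times=t.times.copy(), frequencies=t.frequencies.copy(),
        channels=list(t.channels), conditions=t.conditions.copy(),
        participant_id=t.participant_id, normalization="welded-z",
        baseline_window=(float(window[0]), float(window[1])),
    )


#: conventional band-power measures (band Hz, window ms, ROI)
THETA_MEASURE = ("theta", (4.0, 7.0), (150.0, 450.0), ("FCz",))
DELTA_MEASURE = ("delta", (1.0, 3.0), (200.0, 500.0), ("CPz",))


def score_band_power(
    t: TFRArray,
    band: tuple[float, float],
    window: tuple[float, float],
    roi: tuple[str, ...],
    name: str | None = None,
) -> SingleTrialScores:
    """Mean welded-z power over a band, window and ROI, per trial."""
    if t.normalization != "welded-z":
        raise EpochsError("band power is scored on welded-z normalized power")
    fmask = (t.frequencies >= band[0] - 1e-9) & (t.frequencies <= band[1] + 1e-9)
    if not fmask.any():
        raise EpochsError(
            f"band {band} contains no bank frequency; bank frequencies are "
            f"{np.round(t.frequencies, 3).tolist()}")
    idx = []
    for ch in roi:
        if ch not in t.channels:
            raise EpochsError(f"ROI channel {ch} not in TFR array")
        idx.append(t.channels.index(ch))
    tmask = t.time_mask(window)
    vals = t.power[:, idx][:, :, fmask][:, :, :, tmask].mean(axis=(1, 2, 3))
    tab = pd.DataFrame({"participant": t.participant_id,
                        "trial": np.arange(t.power.shape[0])})
    for col in CONDITION_COLUMNS:
        tab[col] = t.conditions[col].to_numpy()
    tab["value"] = vals
    label = name or f"power_{band[0]:g}_{band[1]:g}"
    return SingleTrialScores(table=tab, measure=label, units="welded-z")
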