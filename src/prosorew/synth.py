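"""Synthetic cohort generator for the 2x2x2 prosocial reward design.

Each simulated participant produces feedback-locked epochs plus post-task
liking ratings with a fully known effect structure:

* ERP-like components (reward positivity, P3) are monophasic deflections —
  a temporal Gaussian at a component-specific peak latency multiplied by a
  spatial Gaussian centred on a scalp site.
* Oscillatory bursts (delta, theta) are Gaussian-enveloped sinusoids with a
  random uniform phase per trial, so by default they survive in single-trial
  power but largely cancel in the across-trial ERP average; a phase-locked
  fraction is configurable.
* Per-trial component amplitudes follow the factorial model: population term
  coefficients (intercept, three mains, three two-ways, one three-way) plus
  participant-level random deviations on a configurable subset of terms plus
  trial-level Gaussian noise.
* Background activity is 1/f ("pink") noise produced by spectral shaping of
  white noise, plus white sensor noise; four artifact classes (step, range,
  flatline, drift) can be injected at configurable per-trial rates.

Everything is driven by a single integer seed; identical seeds give
bit-identical output.  The emitted :class:`GroundTruth` records every
realised coefficient, noiseless per-trial amplitude, and artifact flag, so
downstream recovery tests can compare against exactly what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as dz
from .design import TERMS
from .epochs import EpochSet
from .layout import default_layout

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

ARTIFACT_KINDS = ("step", "range", "flatline", "drift")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class DesignSpec:
    """Experimental design of the simulated cohort."""

    n_participants: int = 40
    n_trials_per_cell: int = 40
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-1500.0, 2000.0)
    channels: list[str] = field(default_factory=lambda: default_layout()[0])
    positions: np.ndarray = field(default_factory=lambda: default_layout()[1])

    def __post_init__(self) -> None:
        if self.n_trials_per_cell < 1:
            raise ConfigurationError("n_trials_per_cell must be >= 1")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("duplicate channel names in layout")
        for roi in ("Fz", "FCz", "Cz", "CPz", "Pz"):
            if roi not in self.channels:
                raise ConfigurationError(f"required ROI channel {roi} missing")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channels), 2):
            raise ConfigurationError("positions must be (n_channels, 2)")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_cell * dz.N_CELLS

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        lo, hi = self.epoch_window
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)


@dataclass
class ComponentShape:
    """Spatiotemporal template of one signal family."""

    peak_ms: float
    fwhm_ms: float
    channel: str
    spatial_spread: float = 0.35          # head-radius units
    burst_freq_hz: float | None = None    # None -> monophasic deflection
    phase_locked_frac: float = 0.0        # of trials, for bursts


@dataclass
class FamilyEffect:
    """Effect structure of one signal family.

    ``coeffs`` holds the population term coefficients (μV for EEG families,
    rating points for the rating family) in the order of
    :data:`prosorew.design.TERMS`; ``participant_sd`` the between-participant
    SD per term; ``trial_noise_sd`` the trial-level amplitude noise.
    """

    coeffs: dict[str, float]
    participant_sd: dict[str, float]
    trial_noise_sd: float
    shape: ComponentShape | None = None

    def coeff_vector(self) -> np.ndarray:
        return np.array([self.coeffs.get(t, 0.0) for t in TERMS])

    def sd_vector(self) -> np.ndarray:
        sd = np.array([self.participant_sd.get(t, 0.0) for t in TERMS])
        if (sd < 0).any() or self.trial_noise_sd < 0:
            raise ConfigurationError("SDs must be nonnegative")
        return sd

    @classmethod
    def from_cell_means(cls, cell_means, **kw) -> "FamilyEffect":
        vec = dz.cell_means_to_coeffs(np.asarray(cell_means, dtype=float))
        return cls(coeffs=dict(zip(TERMS, vec)), **kw)


@dataclass
class EffectSpec:
    """Effect structure for every signal family (keyed by family name)."""

    families: dict[str, FamilyEffect]

    def __post_init__(self) -> None:
        for name, fam in self.families.items():
            fam.sd_vector()  # validates


@dataclass
class NoiseSpec:
    """Background noise and artifact injection settings."""

    pink_exponent: float = 1.0
    pink_amplitude: float = 10.0   # μV RMS of the 1/f background
    pink_high_cut_hz: float = 60.0 # Gaussian spectral roll-off of the background
    white_sd: float = 2.0          # μV white sensor noise
    artifact_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pink_amplitude < 0 or self.white_sd < 0:
            raise ConfigurationError("noise amplitudes must be nonnegative")
        for k, r in self.artifact_rates.items():
            if k not in ARTIFACT_KINDS:
                raise ConfigurationError(f"unknown artifact kind {k!r}")
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"artifact rate for {k} outside [0,1]")


@dataclass
class GroundTruth:
    """Everything that was actually injected for one participant."""

    participant_coeffs: dict[str, np.ndarray]     # family -> 8 realised terms
    trial_amplitudes: dict[str, np.ndarray]       # family -> noiseless+noise amp per trial
    noiseless_cell_means: dict[str, np.ndarray]   # family -> 8 cell means (realised)
    artifact_flags: dict[str, np.ndarray]         # kind -> bool per trial
    rating_cell_means: np.ndarray | None = None   # realised latent rating means


@dataclass
class ParticipantBundle:
    epochs: EpochSet
    ratings: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# defaults: effect pattern mimicking an egoism bias that vanishes with delay
# ---------------------------------------------------------------------------

def default_effects() -> EffectSpec:
    """Default effect structure.

    The ERP coefficient defaults reproduce the qualitative published pattern
    for this task family — a magnitude effect that is larger on
    self-benefiting than other-benefiting trials when rewards are immediate
    and comparable when they are delayed (positive three-way term), with the
    reward-positivity magnitude term at 2.49 μV used as the demonstration
    default.  Burst amplitudes are in μV; their normalized-power effect
    sizes are emergent, not specified directly.
    """
    return EffectSpec(families={
        "rewp": FamilyEffect(
            coeffs={"intercept": 4.0, "beneficiary": -2.51, "magnitude": 2.49,
                    "time": -0.61, "beneficiary:magnitude": -1.16,
                    "beneficiary:magnitude:time": 1.61},
            participant_sd={"intercept": 2.0, "beneficiary": 0.8,
                            "magnitude": 0.8, "time": 0.8},
            trial_noise_sd=8.0,
            shape=ComponentShape(peak_ms=310.0, fwhm_ms=100.0, channel="FCz"),
        ),
        "p3": FamilyEffect(
            coeffs={"intercept": 5.0, "beneficiary": -2.69, "magnitude": 2.48,
                    "time": -0.54, "magnitude:time": -1.28,
                    "beneficiary:magnitude:time": 2.02},
            participant_sd={"intercept": 2.0, "beneficiary": 0.8,
                            "magnitude": 0.8, "time": 0.8},
            trial_noise_sd=8.0,
            shape=ComponentShape(peak_ms=370.0, fwhm_ms=120.0, channel="Pz"),
        ),
        "theta": FamilyEffect(
            coeffs={"intercept": 3.0, "beneficiary": -0.6, "time": 0.4,
                    "beneficiary:magnitude": 0.8},
            participant_sd={"intercept": 1.0, "beneficiary": 0.4,
                            "magnitude": 0.4, "time": 0.4},
            trial_noise_sd=2.0,
            shape=ComponentShape(peak_ms=300.0, fwhm_ms=300.0, channel="FCz",
                                 burst_freq_hz=5.5),
        ),
        "delta": FamilyEffect(
            coeffs={"intercept": 4.0, "beneficiary": -1.5, "magnitude": 2.0,
                    "beneficiary:magnitude": -1.2,
                    "beneficiary:magnitude:time": 1.2},
            participant_sd={"intercept": 1.0, "beneficiary": 0.4,
                            "magnitude": 0.4, "time": 0.4},
            trial_noise_sd=2.0,
            shape=ComponentShape(peak_ms=350.0, fwhm_ms=400.0, channel="CPz",
                                 burst_freq_hz=2.0),
        ),
        "rating": FamilyEffect(
            coeffs={"intercept": 5.5, "magnitude": 2.0, "time": -0.8,
                    "beneficiary:magnitude": -0.4, "beneficiary:time": -0.3,
                    "beneficiary:magnitude:time": 0.8},
            participant_sd={"intercept": 1.0, "beneficiary": 0.3,
                            "magnitude": 0.3, "time": 0.3},
            trial_noise_sd=0.8,
            shape=None,
        ),
    })


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _spatial_profile(design: DesignSpec, shape: ComponentShape) -> np.ndarray:
    if shape.channel not in design.channels:
        raise ConfigurationError(f"component channel {shape.channel} not in layout")
    center = design.positions[design.channels.index(shape.channel)]
    d2 = ((design.positions - center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * shape.spatial_spread ** 2))


def _check_component_window(name: str, shape: ComponentShape,
                            design: DesignSpec) -> None:
    lo = shape.peak_ms - shape.fwhm_ms
    hi = shape.peak_ms + shape.fwhm_ms
    if lo < design.epoch_window[0] or hi > design.epoch_window[1]:
        raise ConfigurationError(
            f"component {name!r} window {lo:.0f}..{hi:.0f} ms lies outside "
            f"epoch window {design.epoch_window}")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_times: int, exponent: float, rms: float,
                sfreq: float, high_cut_hz: float = 60.0) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, RMS-normalised per trace.

    A Gaussian roll-off above ``high_cut_hz`` emulates the steep fall of
    scalp-EEG spectra (tissue filtering plus the acquisition low-pass);
    without it the shaped noise keeps enough broadband energy to produce
    unphysiological sample-to-sample steps.
    """
    white = rng.standard_normal(shape + (n_times,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    gain = np.ones_like(freqs)
    gain[1:] = (freqs[1:] ** (-exponent / 2.0)
                * np.exp(-((freqs[1:] / high_cut_hz) ** 2)))
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n_times, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return rms * shaped / scale


def simulate_participant(
    design: DesignSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    seed: int,
    participant_id: str = "p00",
) -> ParticipantBundle:
    """Simulate one participant: epochs, liking ratings and ground truth."""
    rng = np.random.default_rng(seed)
    times = design.times()
    n_t = times.size
    n_tr = design.n_trials
    n_ch = len(design.channels)

    # trial sequence: each cell n_trials_per_cell times, pseudorandom order
    cells = np.repeat(np.arange(dz.N_CELLS), design.n_trials_per_cell)
    cells = rng.permutation(cells)
    conditions = dz.conditions_frame(cells)
    X_cell = dz.design_matrix()          # 8 x 8
    X_trial = X_cell[cells]              # trial x 8

    data = np.zeros((n_tr, n_ch, n_t))
    part_coeffs: dict[str, np.ndarray] = {}
    trial_amp: dict[str, np.ndarray] = {}
    cell_means: dict[str, np.ndarray] = {}
    rating_means = None
    ratings = None

    for name in sorted(effects.families):
        fam = effects.families[name]
        beta = fam.coeff_vector() + rng.standard_normal(len(TERMS)) * fam.sd_vector()
        part_coeffs[name] = beta
        cell_means[name] = X_cell @ beta

        if fam.shape is None:  # rating family: one latent draw per cell
            rating_means = cell_means[name]
            noise_r = (rng.standard_normal(dz.N_CELLS) * fam.trial_noise_sd
                       if fam.trial_noise_sd > 0 else np.zeros(dz.N_CELLS))
            vals = np.clip(np.round(rating_means + noise_r), 1, 9).astype(int)
            ratings = dz.cell_table().copy()
            ratings["rating"] = vals
            ratings["participant"] = participant_id
            continue

        _check_component_window(name, fam.shape, design)
        amp = X_trial @ beta
        if fam.trial_noise_sd > 0:
            amp = amp + rng.standard_normal(n_tr) * fam.trial_noise_sd
        trial_amp[name] = amp

        sigma_t = fam.shape.fwhm_ms * FWHM_TO_SIGMA
        env = np.exp(-((times - fam.shape.peak_ms) ** 2) / (2.0 * sigma_t ** 2))
        spatial = _spatial_profile(design, fam.shape)

        if fam.shape.burst_freq_hz is None:
            data += amp[:, None, None] * spatial[None, :, None] * env[None, None, :]
        else:
            phase = rng.uniform(0.0, 2 * np.pi, size=n_tr)
            if fam.shape.phase_locked_frac > 0:
                locked = rng.random(n_tr) < fam.shape.phase_locked_frac
                phase[locked] = 0.0
            carrier = np.sin(
                2 * np.pi * fam.shape.burst_freq_hz
                * (times[None, :] - fam.shape.peak_ms) / 1000.0
                + phase[:, None]
            )
            data += (amp[:, None, None] * spatial[None, :, None]
                     * (env[None, :] * carrier)[:, None, :])

    if ratings is None:
        ratings = dz.cell_table().copy()
        ratings["rating"] = np.nan
        ratings["participant"] = participant_id

    # background noise
    if noise.pink_amplitude > 0:
        data += _pink_noise(rng, (n_tr, n_ch), n_t, noise.pink_exponent,
                            noise.pink_amplitude, design.sampling_rate,
                            noise.pink_high_cut_hz)
    if noise.white_sd > 0:
        data += rng.standard_normal((n_tr, n_ch, n_t)) * noise.white_sd

    # artifact injection (flags drawn in fixed kind order for determinism)
    flags: dict[str, np.ndarray] = {}
    for kind in ARTIFACT_KINDS:
        rate = noise.artifact_rates.get(kind, 0.0)
        flags[kind] = (rng.random(n_tr) < rate) if rate > 0 else np.zeros(n_tr, bool)
    _inject_artifacts(data, flags, times, rng)

    epochs = EpochSet(
        data=data, times=times, channels=list(design.channels),
        positions=design.positions.copy(), conditions=conditions,
        participant_id=participant_id,
    )
    truth = GroundTruth(
        participant_coeffs=part_coeffs, trial_amplitudes=trial_amp,
        noiseless_cell_means=cell_means, artifact_flags=flags,
        rating_cell_means=rating_means,
    )
    return ParticipantBundle(epochs=epochs, ratings=ratings, truth=truth)


def _inject_artifacts(data: np.ndarray, flags: dict[str, np.ndarray],
                      times: np.ndarray, rng: np.random.Generator) -> None:
    """Overwrite flagged trials in place so each named violation is present.

    Each injection comfortably exceeds its rule's threshold; an injection may
    incidentally trip additional rules (as real artifacts do).
    """
    n_tr, n_ch, n_t = data.shape
    sfreq = 1000.0 / (times[1] - times[0])
    for i in np.flatnonzero(flags["step"]):
        ch = int(rng.integers(n_ch))
        s = int(rng.integers(n_t // 4, 3 * n_t // 4))
        data[i, ch, s] += 80.0          # one-sample spike: |Δ| = 80 > 50 μV
    for i in np.flatnonzero(flags["range"]):
        ch = int(rng.integers(n_ch))
        w = max(int(round(0.5 * sfreq)), 8)   # smooth 500-ms ramp
        s = int(rng.integers(0, n_t - w))
        ramp = 250.0 * 0.5 * (1 - np.cos(np.linspace(0, np.pi, w)))
        data[i, ch, s : s + w] += ramp        # p2p ≥ 250 > 200 μV, steps small
    for i in np.flatnonzero(flags["flatline"]):
        ch = int(rng.integers(n_ch))
        w = max(int(round(0.15 * sfreq)), 4)  # 150-ms frozen stretch
        s = int(rng.integers(0, n_t - w))
        data[i, ch, s : s + w] = data[i, ch, s]
    for i in np.flatnonzero(flags["drift"]):
        ch = int(rng.integers(n_ch))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[i, ch, :] += sign * 160.0 * np.linspace(0.0, 1.0, n_t)


def simulate_cohort(
    design: DesignSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    master_seed: int,
) -> list[ParticipantBundle]:
    """Simulate the whole cohort with deterministic per-participant seeds."""
    seeds = participant_seeds(master_seed, design.n_participants)
    return [
        simulate_participant(design, effects, noise, int(s), f"p{i:02d}")
        for i, s in enumerate(seeds)
    ]


def participant_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([child.generate_state(1)[0] for child in ss.spawn(n)],
                    dtype=np.uint32)
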