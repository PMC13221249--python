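import numpy as np
import pandas as pd
import pytest

from prosorew import design as dz
from prosorew.epochs import EpochSet
from prosorew.synth import (ComponentShape, DesignSpec, EffectSpec,
                            FamilyEffect, NoiseSpec)


def small_design(**kw) -> DesignSpec:
    defaults = dict(n_participants=4, n_trials_per_cell=4, sampling_rate=250.0,
                    epoch_window=(-1500.0, 2000.0))
    defaults.update(kw)
    return DesignSpec(**defaults)


def silent_noise() -> NoiseSpec:
    return NoiseSpec(pink_amplitude=0.0, white_sd=0.0)


def rewp_only_effects(coeffs=None, participant_sd=None, trial_noise_sd=0.0,
                      **shape_kw) -> EffectSpec:
    """A single deflection family, everything else absent."""
    shape = dict(peak_ms=310.0, fwhm_ms=100.0, channel="FCz")
    shape.update(shape_kw)
    return EffectSpec(families={
        "rewp": FamilyEffect(
            coeffs=coeffs or {"intercept": 5.0},
            participant_sd=participant_sd or {},
            trial_noise_sd=trial_noise_sd,
            shape=ComponentShape(**shape),
        ),
    })


def toy_epochs(data: np.ndarray, sfreq: float = 250.0, t0: float = -200.0,
               cells: np.ndarray | None = None, **kw) -> EpochSet:
    """Wrap a raw (trial, channel, time) array in an EpochSet with a trivial
    layout and a balanced condition table."""
    n_tr, n_ch, n_t = data.shape
    times = t0 + 1000.0 / sfreq * np.arange(n_t)
    channels = [f"ch{i}" for i in range(n_ch)]
    positions = np.column_stack([np.arange(n_ch, dtype=float),
                                 np.zeros(n_ch)])
    if cells is None:
        cells = np.arange(n_tr) % dz.N_CELLS
    return EpochSet(data=data, times=times, channels=channels,
                    positions=positions,
                    conditions=dz.conditions_frame(cells), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
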