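"""Scalp channel layout for the synthetic cohort.

A 62-electrode montage in the extended 10-20 convention: 60 scalp sites plus
the two mastoids (M1/M2) used for re-referencing.  Positions come from the
idealised electrode geometry shipped with MNE-Python and are flattened to
2-D with an azimuthal-equidistant projection (vertex at the origin, nasion
towards +y), which is what the spatial Gaussian component templates and
topography plots operate on.
"""

from __future__ import annotations

import functools

import numpy as np

#: the 60 scalp sites used for topography-based analyses, row by row
SCALP_60: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")

#: full recorded montage: scalp then mastoids
CHANNELS_62: tuple[str, ...] = SCALP_60 + MASTOIDS

ROI_CHANNELS: tuple[str, ...] = ("Fz", "FCz", "Cz", "CPz", "Pz")


@functools.lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("colin27_1005")
    return {k: np.asarray(v, dtype=float) for k, v in montage.get_positions()["ch_pos"].items()}


def positions_2d(channels: tuple[str, ...] | list[str] = CHANNELS_62) -> np.ndarray:
    """2-D positions (head-radius units) for the requested channels.

    Azimuthal-equidistant projection: the polar angle from the vertex becomes
    the planar radius, so Cz sits at the origin and the mastoids fall outside
    the unit circle of the scalp sites.
    """
    pos3d = _montage_positions()
    missing = [ch for ch in channels if ch not in pos3d]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    xyz = np.array([pos3d[ch] for ch in channels])
    # centre on the sphere best fitting the full montage
    all_xyz = np.array([pos3d[ch] for ch in CHANNELS_62])
    center = all_xyz.mean(axis=0)
    v = xyz - center
    r = np.linalg.norm(v, axis=1)
    v = v / r[:, None]
    polar = np.arccos(np.clip(v[:, 2], -1.0, 1.0))  # angle from vertex
    azim = np.arctan2(v[:, 1], v[:, 0])
    # scale so the equator (polar = pi/2) maps to radius 1
    rad = polar / (np.pi / 2)
    return np.column_stack([rad * np.cos(azim), rad * np.sin(azim)])


def default_layout() -> tuple[list[str], np.ndarray]:
    """The default (channel names, 2-D positions) pair for synthesis."""
    return list(CHANNELS_62), positions_2d(CHANNELS_62)
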