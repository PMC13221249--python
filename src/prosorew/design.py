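"""Factorial design coding for the 2x2x2 prosocial reward task.

The task crosses three within-participant, two-level factors:

* ``beneficiary`` — who the reward is for (``self`` coded −0.5, ``other`` +0.5),
* ``magnitude``  — reward size (``small`` −0.5, ``large`` +0.5),
* ``time``       — delivery delay (``immediate`` −0.5, ``delayed`` +0.5).

With this centred ±0.5 coding and a balanced design, a fixed-effect
coefficient equals the corresponding (difference of) cell means, which is
what makes the fitted betas directly interpretable in outcome units.

Cell ordering convention: beneficiary varies slowest, time fastest, so cell
index ``i`` maps to ``(beneficiary[i // 4], magnitude[(i // 2) % 2],
time[i % 2])``.  All RDM serialisations and cell-mean vectors in the package
follow this order.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

FACTORS: tuple[str, ...] = ("beneficiary", "magnitude", "time")

#: factor level -> coded value; the first level of each factor carries −0.5
LEVELS: dict[str, tuple[str, str]] = {
    "beneficiary": ("self", "other"),
    "magnitude": ("small", "large"),
    "time": ("immediate", "delayed"),
}

CODES: dict[str, dict[str, float]] = {
    f: {lv: code for lv, code in zip(LEVELS[f], (-0.5, +0.5))} for f in FACTORS
}

#: model terms in fixed order: intercept, mains, two-ways, three-way
TERMS: tuple[str, ...] = (
    "intercept",
    "beneficiary",
    "magnitude",
    "time",
    "beneficiary:magnitude",
    "beneficiary:time",
    "magnitude:time",
    "beneficiary:magnitude:time",
)

N_CELLS = 8


def cell_table() -> pd.DataFrame:
    """Return the 8-row cell table in the canonical order.

    Columns: the three factor levels plus their coded values
    (``<factor>_coded``).
    """
    rows = []
    for b, m, t in itertools.product(*(LEVELS[f] for f in FACTORS)):
        rows.append(
            {
                "beneficiary": b,
                "magnitude": m,
                "time": t,
                "beneficiary_coded": CODES["beneficiary"][b],
                "magnitude_coded": CODES["magnitude"][m],
                "time_coded": CODES["time"][t],
            }
        )
    return pd.DataFrame(rows)


def term_columns(coded: np.ndarray) -> np.ndarray:
    """Expand coded main-effect columns into the full 8-term model matrix.

    Parameters
    ----------
    coded
        Array of shape ``(n, 3)`` holding the ±0.5 codes for beneficiary,
        magnitude and time.

    Returns
    -------
    Array of shape ``(n, 8)`` with columns ordered as :data:`TERMS`.
    """
    coded = np.asarray(coded, dtype=float)
    b, m, t = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [np.ones_like(b), b, m, t, b * m, b * t, m * t, b * m * t]
    )


def design_matrix() -> np.ndarray:
    """The invertible 8x8 cell-by-term matrix under the canonical ordering."""
    tab = cell_table()
    coded = tab[["beneficiary_coded", "magnitude_coded", "time_coded"]].to_numpy()
    return term_columns(coded)


def coeffs_to_cell_means(coeffs: np.ndarray) -> np.ndarray:
    """Map an 8-vector of term coefficients to the 8 cell means."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (N_CELLS,):
        raise ValueError(f"expected 8 term coefficients, got shape {coeffs.shape}")
    return design_matrix() @ coeffs


def cell_means_to_coeffs(cell_means: np.ndarray) -> np.ndarray:
    """Invert :func:`coeffs_to_cell_means` (exact, the matrix is orthogonal
    up to column scaling)."""
    cell_means = np.asarray(cell_means, dtype=float)
    if cell_means.shape != (N_CELLS,):
        raise ValueError(f"expected 8 cell means, got shape {cell_means.shape}")
    return np.linalg.solve(design_matrix(), cell_means)


def cell_index(beneficiary: str, magnitude: str, time: str) -> int:
    """Index of a design cell in the canonical ordering."""
    ib = LEVELS["beneficiary"].index(beneficiary)
    im = LEVELS["magnitude"].index(magnitude)
    it = LEVELS["time"].index(time)
    return ib * 4 + im * 2 + it


def conditions_frame(cells_per_trial: np.ndarray) -> pd.DataFrame:
    """Build a per-trial condition table from cell indices (canonical order)."""
    tab = cell_table()
    out = tab.iloc[np.asarray(cells_per_trial, dtype=int)].reset_index(drop=True)
    out.index.name = "trial"
    return out
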