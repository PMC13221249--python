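"""Single-trial ERP scoring, grand averages, and split-half reliability.

Scores are mean amplitudes over a fixed window and region of interest (ROI):
the reward positivity is read 260–360 ms after feedback over the
frontocentral pair (Fz, FCz), the P3 320–420 ms over the centroparietal pair
(CPz, Pz).  Window endpoints are inclusive on the sample grid (nearest
sample at or inside each endpoint), so 260–360 ms at 500 Hz covers 51
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import cell_table
from .epochs import CONDITION_COLUMNS, EpochSet, EpochsError


@dataclass(frozen=True)
class MeasureSpec:
    """A named mean-amplitude measure: time window plus channel ROI."""

    name: str
    window: tuple[float, float]
    roi: tuple[str, ...]
    units: str = "uV"


#: conventional feedback-ERP measures
REWP = MeasureSpec("rewp", (260.0, 360.0), ("Fz", "FCz"))
P3 = MeasureSpec("p3", (320.0, 420.0), ("CPz", "Pz"))


@dataclass
class SingleTrialScores:
    """Per-trial scalar scores for one measure and participant.

    ``table`` columns: ``participant``, ``trial``, the six condition columns,
    and ``value``.
    """

    table: pd.DataFrame
    measure: str
    units: str = "uV"

    def __post_init__(self) -> None:
        if self.table["value"].isna().any():
            raise EpochsError("scores contain missing values")

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    def cell_means(self) -> np.ndarray:
        """Mean score per design cell in canonical order."""
        tab = cell_table()
        out = np.empty(len(tab))
        for i, row in tab.iterrows():
            m = ((self.table["beneficiary"] == row["beneficiary"])
                 & (self.table["magnitude"] == row["magnitude"])
                 & (self.table["time"] == row["time"]))
            if not m.any():
                raise EpochsError(
                    f"empty cell {row['beneficiary']}/{row['magnitude']}/"
                    f"{row['time']}")
            out[i] = self.table.loc[m, "value"].mean()
        return out


def concat_scores(scores: list[SingleTrialScores]) -> pd.DataFrame:
    """Stack per-participant score tables into one tidy cohort frame."""
    if not scores:
        raise EpochsError("no scores to concatenate")
    measures = {s.measure for s in scores}
    if len(measures) > 1:
        raise EpochsError(f"mixed measures: {sorted(measures)}")
    return pd.concat([s.table for s in scores], ignore_index=True)


def score_single_trial(
    e: EpochSet, m: MeasureSpec, require_baseline: bool = True
) -> SingleTrialScores:
    """Mean amplitude over ``m.roi`` channels and ``m.window``, per trial."""
    if require_baseline and e.baseline_window is None:
        raise EpochsError(
            f"measure {m.name!r} expects baseline-subtracted epochs")
    idx = [e.channel_index(ch) for ch in m.roi]
    mask = e.time_mask(m.window)
    vals = e.data[:, idx, :][:, :, mask].mean(axis=(1, 2))
    tab = pd.DataFrame({"participant": e.participant_id,
                        "trial": np.arange(e.n_trials)})
    for col in CONDITION_COLUMNS:
        tab[col] = e.conditions[col].to_numpy()
    tab["value"] = vals
    return SingleTrialScores(table=tab, measure=m.name, units=m.units)


def grand_average(
    epoch_sets: list[EpochSet],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-participant grand average per design cell.

    Each participant contributes one unweighted cell-mean waveform per cell;
    the grand average is the mean of those across participants and the SEM
    is their standard deviation (ddof=1) divided by sqrt(n_participants).

    Returns
    -------
    (grand, sem, times)
        ``grand`` and ``sem`` have shape ``(8, n_channels, n_times)`` in the
        canonical cell order.
    """
    if not epoch_sets:
        raise EpochsError("no participants")
    ref = epoch_sets[0]
    for e in epoch_sets[1:]:
        if e.channels != ref.channels or not np.array_equal(e.times, ref.times):
            raise EpochsError("mismatched channel or time axes across participants")
    tab = cell_table()
    per_part = np.empty((len(epoch_sets), len(tab), ref.n_channels,
                         ref.times.size))
    for p, e in enumerate(epoch_sets):
        for i, row in tab.iterrows():
            m = ((e.conditions["beneficiary"] == row["beneficiary"])
                 & (e.conditions["magnitude"] == row["magnitude"])
                 & (e.conditions["time"] == row["time"])).to_numpy()
            if not m.any():
                raise EpochsError(
                    f"participant {e.participant_id} has no trials in cell "
                    f"{row['beneficiary']}/{row['magnitude']}/{row['time']}")
            per_part[p, i] = e.data[m].mean(axis=0)
    grand = per_part.mean(axis=0)
    n = len(epoch_sets)
    sem = (per_part.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros_like(grand)
    return grand, sem, ref.times.copy()


def split_half_reliability(
    scores_by_participant: dict[str, SingleTrialScores],
    n_splits: int = 100,
    seed: int = 0,
    method: str = "random",
    spearman_brown: bool = True,
) -> float:
    """Split-half reliability of a single-trial measure across participants.

    Trials are split into halves within each design cell (stratified), the
    per-participant half means are correlated across participants, and the
    correlation is Spearman-Brown corrected to full length, ``2r/(1+r)``.
    ``method="random"`` averages over ``n_splits`` seeded random splits;
    ``method="oddeven"`` uses the single odd/even split.
    """
    if len(scores_by_participant) < 3:
        raise EpochsError("need at least 3 participants for reliability")
    rng = np.random.default_rng(seed)

    cell_key = ["beneficiary", "magnitude", "time"]
    grouped = {}
    for pid, s in scores_by_participant.items():
        g = {k: v["value"].to_numpy()
             for k, v in s.table.groupby(cell_key, sort=True)}
        for k, v in g.items():
            if v.size < 2:
                raise EpochsError(
                    f"participant {pid} has fewer than 2 trials in cell {k}")
        grouped[pid] = g

    def one_split(split_idx: int) -> float:
        a_means, b_means = [], []
        for pid in sorted(grouped):
            a_vals, b_vals = [], []
            for k in sorted(grouped[pid]):
                v = grouped[pid][k]
                n = v.size
                if method == "oddeven":
                    half_a = np.arange(n) % 2 == 0
                else:
                    perm = rng.permutation(n)
                    half_a = np.zeros(n, bool)
                    half_a[perm[: n // 2]] = True
                a_vals.append(v[half_a])
                b_vals.append(v[~half_a])
            a_means.append(np.concatenate(a_vals).mean())
            b_means.append(np.concatenate(b_vals).mean())
        a = np.asarray(a_means)
        b = np.asarray(b_means)
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    n_iter = 1 if method == "oddeven" else n_splits
    rs = np.array([one_split(i) for i in range(n_iter)], dtype=float)
    rs = rs[~np.isnan(rs)]
    if rs.size == 0:
        raise EpochsError("reliability undefined: no across-participant variance")
    r = float(rs.mean())
    if spearman_brown:
        r = 2.0 * r / (1.0 + r)
    return r
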