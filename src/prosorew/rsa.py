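"""Time-resolved representational similarity analysis (RSA).

At every timepoint the 8 condition-mean topographies (60 scalp channels)
are compared pairwise with the Mahalanobis distance, whitened by a single
pooled residual covariance (trial minus its cell mean, pooled over
timepoints, with Ledoit-Wolf shrinkage toward a scaled identity).  The
8 × 8 neural dissimilarity matrix per timepoint is regressed — upper
triangles vectorized and z-scored — onto the three binary model matrices
for beneficiary, magnitude and time, which are mutually orthogonal for the
full factorial design.  The per-participant coefficient time series are
tested against zero with a one-sample cluster-based sign-flip permutation
test (cluster mass = sum of t inside a contiguous supra-threshold run,
null = maximum cluster mass over random participant-wise sign flips).

Conditioning on reward time ("split" analysis) reduces the design to the
2 × 2 beneficiary × magnitude grid: 4 × 4 matrices with 6-entry upper
triangles and two (still orthogonal) model predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from sklearn.covariance import LedoitWolf

from .design import FACTORS, LEVELS, cell_table
from .epochs import EpochSet, EpochsError
from .layout import SCALP_60


# ---------------------------------------------------------------------------
# model RDMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelRDM:
    """Binary dissimilarity model for one task factor (0 same, 1 different)."""

    name: str
    matrix: np.ndarray

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


def model_rdms(factors: tuple[str, ...] = FACTORS,
               cells: pd.DataFrame | None = None) -> dict[str, ModelRDM]:
    """Model RDMs over the given cell table (default: the full 8 cells)."""
    if cells is None:
        cells = cell_table()
    out = {}
    for f in factors:
        lv = cells[f].to_numpy()
        mat = (lv[:, None] != lv[None, :]).astype(float)
        out[f] = ModelRDM(name=f, matrix=mat)
    return out


# ---------------------------------------------------------------------------
# neural RDMs
# ---------------------------------------------------------------------------

@dataclass
class NeuralRDMSeries:
    """Per-timepoint condition dissimilarity matrices."""

    dist: np.ndarray            # (n_times, n_cells, n_cells)
    times: np.ndarray
    cells: pd.DataFrame

    def upper(self) -> np.ndarray:
        """Upper triangles, shape (n_times, n_pairs)."""
        n = self.dist.shape[1]
        iu = np.triu_indices(n, k=1)
        return self.dist[:, iu[0], iu[1]]


def _cell_assignments(e: EpochSet, cells: pd.DataFrame) -> list[np.ndarray]:
    masks = []
    for _, row in cells.iterrows():
        m = np.ones(e.n_trials, dtype=bool)
        for f in FACTORS:
            if f in cells.columns:
                m &= (e.conditions[f] == row[f]).to_numpy()
        if m.sum() < 2:
            raise EpochsError(
                f"cell {tuple(row[f] for f in FACTORS if f in cells.columns)} "
                "has fewer than 2 trials")
        masks.append(m)
    return masks


def neural_rdm(
    e: EpochSet,
    channels: list[str] | None = None,
    shrinkage: str | float = "ledoit-wolf",
    cells: pd.DataFrame | None = None,
    cov: np.ndarray | None = None,
) -> NeuralRDMSeries:
    """Mahalanobis-distance RDM between condition-mean topographies.

    The whitening covariance is estimated once from trial-level residuals
    (each trial minus its condition mean) pooled over all timepoints.
    ``shrinkage`` is ``"ledoit-wolf"`` (analytic intensity), a float in
    [0, 1] (fixed intensity toward the scaled identity), or 0 for the raw
    sample covariance (which raises if singular).  Passing an explicit
    ``cov`` (channels × channels) bypasses estimation entirely; with the
    identity matrix the distances reduce to Euclidean distances.
    """
    if channels is None:
        channels = [ch for ch in SCALP_60 if ch in e.channels]
    idx = [e.channel_index(ch) for ch in channels]
    data = e.data[:, idx, :]                     # tr × ch × t
    n_ch = len(idx)
    if cells is None:
        cells = cell_table()
    masks = _cell_assignments(e, cells)

    means = np.stack([data[m].mean(axis=0) for m in masks])   # cell × ch × t
    resid = data.copy()
    for m, mu in zip(masks, means):
        resid[m] -= mu[None]

    samples = resid.transpose(0, 2, 1).reshape(-1, n_ch)
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (n_ch, n_ch):
            raise EpochsError(f"cov must be {n_ch}x{n_ch}")
    elif isinstance(shrinkage, str):
        if shrinkage != "ledoit-wolf":
            raise EpochsError(f"unknown shrinkage {shrinkage!r}")
        cov = LedoitWolf(assume_centered=True).fit(samples).covariance_
    else:
        s = float(shrinkage)
        if not 0.0 <= s <= 1.0:
            raise EpochsError("shrinkage intensity must be in [0, 1]")
        emp = samples.T @ samples / samples.shape[0]
        cov = (1 - s) * emp + s * np.trace(emp) / n_ch * np.eye(n_ch)

    ev = np.linalg.eigvalsh(cov)
    if ev.min() <= 1e-10 * max(ev.max(), 1e-300):
        raise EpochsError(
            "covariance is singular; use shrinkage ('ledoit-wolf' or a "
            "positive intensity)")
    chol = np.linalg.cholesky(cov)

    n_cells = means.shape[0]
    n_t = data.shape[2]
    # whiten the means once: solve L w = m  =>  d^2 = ||w_i - w_j||^2
    w = np.empty_like(means)
    for c in range(n_cells):
        w[c] = scipy.linalg.solve_triangular(chol, means[c], lower=True)
    dist = np.zeros((n_t, n_cells, n_cells))
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            d = np.sqrt(((w[i] - w[j]) ** 2).sum(axis=0))
            dist[:, i, j] = d
            dist[:, j, i] = d
    return NeuralRDMSeries(dist=dist, times=e.times.copy(),
                           cells=cells.reset_index(drop=True))


# ---------------------------------------------------------------------------
# RDM regression
# ---------------------------------------------------------------------------

@dataclass
class CodingTimeSeries:
    """Per-timepoint model-RDM regression coefficients for one participant."""

    coef: np.ndarray            # (n_predictors, n_times)
    predictors: list[str]
    times: np.ndarray
    participant_id: str = "p00"


def _zscore(v: np.ndarray, axis=-1) -> np.ndarray:
    mu = v.mean(axis=axis, keepdims=True)
    sd = v.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise EpochsError("cannot z-score a constant RDM vector")
    return (v - mu) / sd


def rdm_regression(
    neural: NeuralRDMSeries, models: dict[str, ModelRDM],
    participant_id: str = "p00",
) -> CodingTimeSeries:
    """Multiple regression of the neural RDM on all model RDMs, per timepoint.

    Upper-triangle vectors of the neural and model matrices are z-scored;
    the neural vector is regressed on all model vectors jointly (with an
    intercept, which is ≈0 after z-scoring).
    """
    names = list(models)
    Xcols = [_zscore(models[n].upper()) for n in names]
    # collinearity check on the z-scored model vectors
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            r = float(np.dot(Xcols[a], Xcols[b]) / len(Xcols[a]))
            if abs(r) > 0.999:
                raise EpochsError(
                    f"model RDMs {names[a]!r} and {names[b]!r} are collinear")
    X = np.column_stack([np.ones(len(Xcols[0]))] + Xcols)
    Y = _zscore(neural.upper(), axis=1)          # (n_times, n_pairs)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return CodingTimeSeries(coef=beta[1:], predictors=names,
                            times=neural.times.copy(),
                            participant_id=participant_id)


# ---------------------------------------------------------------------------
# cluster-based sign-flip permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    t_threshold: float
    seed: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _find_clusters(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous same-sign supra-threshold runs: (start, stop, mass)."""
    out = []
    for sign in (1.0, -1.0):
        supra = sign * t > thr
        i = 0
        n = t.size
        while i < n:
            if supra[i]:
                j = i
                while j + 1 < n and supra[j + 1]:
                    j += 1
                out.append((i, j, float(t[i : j + 1].sum())))
                i = j + 1
            else:
                i += 1
    return sorted(out)


def cluster_permutation(
    coefs: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """One-sample cluster permutation test of a coefficient time series.

    Parameters
    ----------
    coefs
        Array ``(n_participants, n_times)`` of per-participant coefficients.
    n_perm
        Number of random participant-wise sign flips (each participant's
        whole series is flipped coherently).
    alpha_cluster
        Two-sided cluster-forming alpha on the one-sample t statistic.

    The cluster p-value is ``(1 + #{null ≥ observed}) / (1 + n_perm)`` with
    the null defined by the maximum absolute cluster mass per permutation.
    """
    coefs = np.asarray(coefs, dtype=float)
    n_sub, n_t = coefs.shape
    if n_sub < 8:
        raise EpochsError("cluster permutation requires at least 8 participants")
    if n_perm < 500:
        raise EpochsError("use at least 500 permutations")
    thr = scipy.stats.t.ppf(1.0 - alpha_cluster / 2.0, n_sub - 1)

    def tseries(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return m / (sd / np.sqrt(n_sub))

    t_obs = tseries(coefs)
    obs = _find_clusters(t_obs, thr)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        t_p = tseries(coefs * signs[:, None])
        cl = _find_clusters(t_p, thr)
        null[p] = max((abs(m) for *_, m in cl), default=0.0)

    clusters = []
    for i, j, mass in obs:
        pval = (1.0 + float(np.sum(null >= abs(mass)))) / (1.0 + n_perm)
        clusters.append(Cluster(start_ms=float(times[i]), end_ms=float(times[j]),
                                mass=mass, p=pval))
    return ClusterResult(clusters=clusters, n_perm=n_perm,
                         t_threshold=float(thr), seed=seed)


# ---------------------------------------------------------------------------
# cohort pipelines
# ---------------------------------------------------------------------------

def coding_timeseries_cohort(
    epoch_sets: list[EpochSet],
    channels: list[str] | None = None,
    shrinkage: str | float = "ledoit-wolf",
) -> dict[str, np.ndarray]:
    """Full-design RDM regression per participant.

    Returns predictor -> array ``(n_participants, n_times)``.
    """
    models = model_rdms()
    stacks: dict[str, list[np.ndarray]] = {f: [] for f in FACTORS}
    for e in epoch_sets:
        n = neural_rdm(e, channels=channels, shrinkage=shrinkage)
        c = rdm_regression(n, models, participant_id=e.participant_id)
        for k, name in enumerate(c.predictors):
            stacks[name].append(c.coef[k])
    return {name: np.vstack(v) for name, v in stacks.items()}


def rsa_by_time_condition(
    epoch_sets: list[EpochSet],
    channels: list[str] | None = None,
    shrinkage: str | float = "ledoit-wolf",
) -> dict[str, dict[str, np.ndarray]]:
    """Beneficiary/magnitude RDM regression separately per reward-time level.

    Within each level of the split factor the design collapses to the
    2 × 2 beneficiary × magnitude grid (4 × 4 RDMs, 6-entry upper triangle,
    2 orthogonal model predictors).

    Returns level -> predictor -> ``(n_participants, n_times)``.
    """
    sub_factors = ("beneficiary", "magnitude")
    full = cell_table()
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for level in LEVELS["time"]:
        cells = (full[full["time"] == level]
                 .drop_duplicates(subset=list(sub_factors))
                 .reset_index(drop=True))
        models = model_rdms(sub_factors, cells)
        stacks: dict[str, list[np.ndarray]] = {f: [] for f in sub_factors}
        for e in epoch_sets:
            keep = (e.conditions["time"] == level).to_numpy()
            if not keep.any():
                raise EpochsError(f"no trials at time level {level!r}")
            es = e.select_trials(np.flatnonzero(keep))
            n = neural_rdm(es, channels=channels, shrinkage=shrinkage,
                           cells=cells)
            c = rdm_regression(n, models, participant_id=e.participant_id)
            for k, name in enumerate(c.predictors):
                stacks[name].append(c.coef[k])
        out[level] = {name: np.vstack(v) for name, v in stacks.items()}
    return out
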