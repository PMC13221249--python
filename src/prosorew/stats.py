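"""Factorial statistical layer: mixed models, contrasts, ANOVA, correlations.

Single-trial scores are modelled with linear mixed-effects regression:
fixed effects are the three centred ±0.5-coded factors (beneficiary,
magnitude, time) and all their interactions; random effects start from the
maximal declared structure (by-participant intercept plus slopes for the
three first-level factors, fully correlated) and, whenever the fit is
singular or fails to converge, are simplified deterministically — first the
random-effect correlations are dropped, then the slope with the smallest
estimated variance, repeated until the model converges.  The trail of
dropped terms is recorded on the result.  Estimation is by restricted
maximum likelihood (REML); fixed-effect p-values use the normal
approximation for t = β/SE (an optional reference df can be supplied for a
t-based p-value).

Interaction decomposition uses estimated-marginal-mean style contrasts
formed as linear combinations of the fixed effects under the ±0.5 coding,
with covariance-propagated standard errors and Benjamini-Hochberg FDR
correction within each contrast family.  Liking ratings get a classical
2×2×2 within-participant ANOVA (each term's F equals the squared paired t
of the participant-level contrast).  Cross-participant Pearson correlations
of the magnitude effect (large − small) between self- and other-benefiting
trials, separately for immediate and delayed rewards, are compared with a
Fisher r-to-z two-sample statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.multitest import multipletests

from .design import LEVELS, TERMS, term_columns
from .epochs import EpochsError

RANDOM_SLOPES = ("beneficiary", "magnitude", "time")


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedFitResult:
    """Fixed-effect table plus random-structure simplification trail."""

    table: pd.DataFrame            # term, beta, se, stat, p
    trail: list[str]
    converged: bool
    measure: str = ""
    cov_fixed: np.ndarray | None = None

    def beta(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])


def _prepare(scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    need = {"participant", "beneficiary_coded", "magnitude_coded",
            "time_coded", "value"}
    missing = need - set(scores.columns)
    if missing:
        raise EpochsError(f"score table missing columns {sorted(missing)}")
    coded = scores[["beneficiary_coded", "magnitude_coded",
                    "time_coded"]].to_numpy(dtype=float)
    X = term_columns(coded)
    y = scores["value"].to_numpy(dtype=float)
    groups = scores["participant"].to_numpy()
    return X, y, groups


def _try_fit(y, X, groups, re_cols, diagonal):
    """One MixedLM fit; returns (result, ok) where ok means converged and
    non-singular."""
    exog_re = X[:, re_cols] if re_cols else np.ones((len(y), 1))
    mod = MixedLM(y, X, groups=groups, exog_re=exog_re)
    k_re = exog_re.shape[1]
    kwargs = {"reml": True, "method": ["lbfgs", "bfgs", "cg"]}
    if diagonal and k_re > 1:
        kwargs["free"] = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(k_re))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = mod.fit(**kwargs)
        except (np.linalg.LinAlgError, ValueError):
            return None, False
    ok = bool(res.converged)
    if ok:
        ev = np.linalg.eigvalsh(res.cov_re)
        scale = max(float(res.scale), 1e-12)
        if ev.min() < 1e-6 * scale:
            ok = False                      # singular random-effect covariance
    return res, ok


def fit_mixed(
    scores: pd.DataFrame,
    measure: str = "",
    df: float | None = None,
) -> MixedFitResult:
    """Fit the factorial mixed model with deterministic simplification.

    Parameters
    ----------
    scores
        Tidy cohort table with ``participant``, the three ``*_coded``
        columns and ``value`` (one row per retained trial).
    df
        Optional reference degrees of freedom; if given, p-values use a t
        distribution with this df instead of the normal approximation.
    """
    X, y, groups = _prepare(scores)
    if len(np.unique(groups)) < 2:
        raise EpochsError("mixed model needs at least 2 participants")
    # fit on a standardized outcome (unit variance) for optimizer stability;
    # estimates are rescaled back to outcome units below
    y_scale = float(y.std())
    if y_scale == 0:
        y_scale = 1.0
    y = y / y_scale

    # ladder: maximal -> no correlations -> drop smallest slope -> ... ->
    # intercept only; first healthy (converged, non-singular) fit wins
    slope_idx = {name: TERMS.index(name) for name in RANDOM_SLOPES}
    active = list(RANDOM_SLOPES)
    trail: list[str] = []
    fallback = None          # best converged-but-singular fit seen

    def cols(slopes):
        return [0] + [slope_idx[s] for s in slopes]

    res, ok = _try_fit(y, X, groups, cols(active), diagonal=False)
    if not ok:
        if res is not None and res.converged and fallback is None:
            fallback = (res, list(trail))
        trail.append("dropped random-effect correlations")
        res, ok = _try_fit(y, X, groups, cols(active), diagonal=True)
    while not ok:
        if res is not None and res.converged and fallback is None:
            fallback = (res, list(trail))
        if not active:
            break
        if res is not None and res.cov_re.shape[0] == len(active) + 1:
            variances = np.diag(res.cov_re)[1:]
            drop = active[int(np.argmin(variances))]
        else:
            drop = active[-1]
        active.remove(drop)
        trail.append(f"dropped random slope for {drop}")
        res, ok = _try_fit(y, X, groups, cols(active), diagonal=True)
    if not ok:
        if fallback is not None:
            # a converged fit with a boundary (singular) random-effect
            # covariance is usable for fixed effects; keep it and say so
            res, trail = fallback
            trail.append("accepted converged fit with singular "
                         "random-effect covariance")
        elif res is None:
            raise EpochsError(
                "mixed model failed even with a random intercept only; "
                "check the score table for degenerate structure")

    beta = np.asarray(res.fe_params, dtype=float) * y_scale
    se = np.asarray(res.bse_fe, dtype=float) * y_scale
    stat = beta / se
    if df is None:
        p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(stat), df)
    table = pd.DataFrame({"term": list(TERMS), "beta": beta, "se": se,
                          "stat": stat, "p": p})
    cov_fixed = (np.asarray(res.cov_params())[: len(TERMS), : len(TERMS)]
                 * y_scale ** 2)
    return MixedFitResult(table=table, trail=trail, converged=bool(res.converged),
                          measure=measure, cov_fixed=cov_fixed)


# ---------------------------------------------------------------------------
# EMM-style interaction contrasts
# ---------------------------------------------------------------------------

CONTRAST_FAMILIES = (
    "simple_magnitude",             # magnitude effect per beneficiary×time cell
    "ben_by_mag_within_time",       # beneficiary×magnitude interaction per time
    "mag_by_time_within_beneficiary",
)


def _contrast_vectors(family: str) -> list[tuple[str, np.ndarray]]:
    """Contrast weights over the 8 fixed-effect terms (canonical order)."""
    i = {t: k for k, t in enumerate(TERMS)}
    out = []
    if family == "simple_magnitude":
        for b_lv, b in zip(LEVELS["beneficiary"], (-0.5, 0.5)):
            for t_lv, t in zip(LEVELS["time"], (-0.5, 0.5)):
                c = np.zeros(8)
                c[i["magnitude"]] = 1.0
                c[i["beneficiary:magnitude"]] = b
                c[i["magnitude:time"]] = t
                c[i["beneficiary:magnitude:time"]] = b * t
                out.append((f"magnitude | {b_lv}, {t_lv}", c))
    elif family == "ben_by_mag_within_time":
        for t_lv, t in zip(LEVELS["time"], (-0.5, 0.5)):
            c = np.zeros(8)
            c[i["beneficiary:magnitude"]] = 1.0
            c[i["beneficiary:magnitude:time"]] = t
            out.append((f"beneficiary:magnitude | {t_lv}", c))
    elif family == "mag_by_time_within_beneficiary":
        for b_lv, b in zip(LEVELS["beneficiary"], (-0.5, 0.5)):
            c = np.zeros(8)
            c[i["magnitude:time"]] = 1.0
            c[i["beneficiary:magnitude:time"]] = b
            out.append((f"magnitude:time | {b_lv}", c))
    else:
        raise EpochsError(f"unknown contrast family {family!r}; "
                          f"choose from {CONTRAST_FAMILIES}")
    return out


def emm_contrasts(fit: MixedFitResult, family: str) -> pd.DataFrame:
    """Estimated-marginal-mean style contrasts with BH-FDR within family."""
    if fit.cov_fixed is None:
        raise EpochsError("fit carries no fixed-effect covariance")
    beta = fit.table["beta"].to_numpy()
    rows = []
    for label, c in _contrast_vectors(family):
        est = float(c @ beta)
        var = float(c @ fit.cov_fixed @ c)
        se = np.sqrt(var)
        z = est / se
        rows.append({"contrast": label, "estimate": est, "se": se, "z": z,
                     "p": 2.0 * scipy.stats.norm.sf(abs(z))})
    tab = pd.DataFrame(rows)
    tab["p_fdr"] = fdr_bh(tab["p"].to_numpy())
    tab["family"] = family
    return tab


# ---------------------------------------------------------------------------
# repeated-measures ANOVA on ratings
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    table: pd.DataFrame            # term, F, df1, df2, p, eta_p2
    degenerate_terms: list[str] = field(default_factory=list)


def rm_anova(ratings: pd.DataFrame) -> AnovaResult:
    """Classical 2×2×2 within-participant ANOVA.

    ``ratings`` is a tidy table with ``participant``, the three factor-level
    columns and ``rating``.  For two-level within factors each term's F is
    the squared paired t of the participant-level contrast (numerically
    identical to the sums-of-squares decomposition), with df (1, n−1) and
    partial eta squared F/(F + df2).  A term whose contrast has zero
    between-participant variance but a nonzero mean is reported with
    ``F = inf`` and listed in ``degenerate_terms``.
    """
    need = {"participant", "beneficiary", "magnitude", "time", "rating"}
    missing = need - set(ratings.columns)
    if missing:
        raise EpochsError(f"rating table missing columns {sorted(missing)}")
    wide = ratings.pivot_table(index="participant", values="rating",
                               columns=["beneficiary", "magnitude", "time"])
    if wide.isna().any().any():
        raise EpochsError("rating table has missing cells")
    # canonical cell order
    cols = [(b, m, t)
            for b in LEVELS["beneficiary"]
            for m in LEVELS["magnitude"]
            for t in LEVELS["time"]]
    Y = wide[cols].to_numpy(dtype=float)          # participants × 8
    n = Y.shape[0]
    if n < 2:
        raise EpochsError("ANOVA needs at least 2 participants")
    from .design import design_matrix
    Xc = design_matrix()                          # 8 cells × 8 terms
    rows, degenerate = [], []
    for k, term in enumerate(TERMS):
        if term == "intercept":
            continue
        w = Xc[:, k]
        contrast = Y @ w / (np.abs(w).sum() / 2.0)   # mean difference scale
        m = contrast.mean()
        sd = contrast.std(ddof=1)
        df2 = n - 1
        if sd == 0:
            if m == 0:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
                degenerate.append(term)
        else:
            t = m / (sd / np.sqrt(n))
            F = t * t
            p = 2.0 * scipy.stats.t.sf(abs(t), df2)
        eta = F / (F + df2) if np.isfinite(F) else 1.0
        rows.append({"term": term, "F": F, "df1": 1, "df2": df2, "p": p,
                     "eta_p2": eta})
    return AnovaResult(table=pd.DataFrame(rows), degenerate_terms=degenerate)


# ---------------------------------------------------------------------------
# magnitude-effect correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationComparison:
    measure: str
    r_immediate: float
    p_immediate: float
    r_delayed: float
    p_delayed: float
    z_comparison: float
    p_comparison: float
    n: int
    p_immediate_fdr: float = np.nan
    p_delayed_fdr: float = np.nan


def _magnitude_effects(scores: pd.DataFrame) -> pd.DataFrame:
    """Per participant × beneficiary × time: mean(large) − mean(small)."""
    cell = scores.groupby(["participant", "beneficiary", "time", "magnitude"],
                          sort=True)["value"].mean().unstack("magnitude")
    if cell.isna().any().any():
        raise EpochsError("a participant has an empty beneficiary×magnitude×"
                          "time cell")
    eff = (cell["large"] - cell["small"]).rename("effect").reset_index()
    return eff


def magnitude_effect_correlations(
    scores_by_measure: dict[str, pd.DataFrame],
) -> list[CorrelationComparison]:
    """Self-other correlations of the reward-magnitude effect, by time level.

    For each measure: per participant the magnitude effect (large − small)
    is computed within each beneficiary × time cell; across participants the
    self vs other effects are Pearson-correlated separately for immediate
    and delayed rewards.  BH-FDR is applied over the whole family (all
    measures × both time levels), and the two correlations are compared with
    z = (z1 − z2)/sqrt(2/(n − 3)) on Fisher-transformed values (a two-sample
    approximation that ignores the dependence between the correlations).
    """
    out: list[CorrelationComparison] = []
    for measure, scores in scores_by_measure.items():
        eff = _magnitude_effects(scores)
        n = eff["participant"].nunique()
        if n < 3:
            raise EpochsError("correlations need at least 3 participants")
        rs = {}
        for t_lv in LEVELS["time"]:
            sub = eff[eff["time"] == t_lv].pivot(
                index="participant", columns="beneficiary", values="effect")
            r, p = scipy.stats.pearsonr(sub["self"], sub["other"])
            rs[t_lv] = (float(r), float(p))
        r1, p1 = rs["immediate"]
        r2, p2 = rs["delayed"]
        z1, z2 = np.arctanh(np.clip([r1, r2], -0.999999, 0.999999))
        z = (z1 - z2) / np.sqrt(2.0 / (n - 3))
        out.append(CorrelationComparison(
            measure=measure, r_immediate=r1, p_immediate=p1,
            r_delayed=r2, p_delayed=p2, z_comparison=float(z),
            p_comparison=float(2.0 * scipy.stats.norm.sf(abs(z))), n=n))
    # one FDR family across all measures and both time levels
    praw = np.array([[c.p_immediate, c.p_delayed] for c in out]).ravel()
    padj = fdr_bh(praw).reshape(-1, 2)
    for c, (pi, pdel) in zip(out, padj):
        c.p_immediate_fdr = float(pi)
        c.p_delayed_fdr = float(pdel)
    return out
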