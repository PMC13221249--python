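"""Mixed models, EMM contrasts, within-participant ANOVA, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from prosorew import design as dz
from prosorew import stats
from prosorew.epochs import EpochsError
from prosorew.stats import (MixedFitResult, emm_contrasts, fdr_bh, fit_mixed,
                            magnitude_effect_correlations, rm_anova)


def _score_table(rng, n_sub, n_per_cell, coeffs, subj_sd=None, noise_sd=0.0):
    """Single-trial scores drawn from the factorial model."""
    subj_sd = subj_sd or {}
    beta = np.array([coeffs.get(t, 0.0) for t in dz.TERMS])
    sd = np.array([subj_sd.get(t, 0.0) for t in dz.TERMS])
    cells = np.tile(np.repeat(np.arange(8), n_per_cell), 1)
    X = dz.design_matrix()[cells]
    rows = []
    for s in range(n_sub):
        b = beta + rng.standard_normal(8) * sd
        y = X @ b + rng.normal(0, noise_sd, cells.size)
        tab = dz.conditions_frame(cells).copy()
        tab["participant"] = f"p{s:03d}"
        tab["value"] = y
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


class TestFitMixed:
    def test_noiseless_balanced_betas_are_exact(self, rng):
        scores = _score_table(rng, 6, 4, {"intercept": 1.0, "magnitude": 2.0})
        fit = fit_mixed(scores)
        assert fit.beta("magnitude") == pytest.approx(2.0, abs=1e-8)
        assert fit.beta("intercept") == pytest.approx(1.0, abs=1e-8)
        for term in ("beneficiary", "time", "beneficiary:magnitude:time"):
            assert fit.beta(term) == pytest.approx(0.0, abs=1e-8)

    def test_betas_equal_cell_mean_contrasts_in_balanced_design(self, rng):
        """Under balanced ±0.5 coding the fixed effects equal the cell-mean
        contrasts from a brute-force cell-means oracle."""
        scores = _score_table(
            rng, 10, 6,
            {"intercept": 3.0, "beneficiary": -1.2, "magnitude": 2.2,
             "beneficiary:magnitude:time": 1.0},
            subj_sd={"intercept": 1.0}, noise_sd=2.0)
        fit = fit_mixed(scores)
        # oracle: per-participant cell means -> coefficients, averaged
        per_sub = []
        for pid, g in scores.groupby("participant"):
            cm = g.groupby(["beneficiary", "magnitude", "time"],
                           sort=True)["value"].mean()
            order = dz.cell_table()
            cm = cm.loc[list(zip(order["beneficiary"], order["magnitude"],
                                 order["time"]))].to_numpy()
            per_sub.append(dz.cell_means_to_coeffs(cm))
        oracle = np.mean(per_sub, axis=0)
        got = fit.table["beta"].to_numpy()
        np.testing.assert_allclose(got, oracle, atol=0.02)

    def test_threeway_recovery_within_3se(self, rng):
        gamma = 1.5
        scores = _score_table(
            rng, 40, 10,
            {"intercept": 4.0, "magnitude": 2.0,
             "beneficiary:magnitude:time": gamma},
            subj_sd={"intercept": 2.0, "beneficiary": 0.5, "magnitude": 0.5,
                     "time": 0.5},
            noise_sd=6.0)
        fit = fit_mixed(scores, measure="rewp")
        row = fit.table.set_index("term").loc["beneficiary:magnitude:time"]
        assert abs(row["beta"] - gamma) < 3 * row["se"]

    def test_simplification_trail_recorded_on_singular_fit(self, rng):
        # no slope variance at all -> the maximal fit is singular
        scores = _score_table(rng, 8, 4, {"intercept": 1.0},
                              subj_sd={"intercept": 1.0}, noise_sd=1.0)
        fit = fit_mixed(scores)
        assert fit.trail  # at least the correlations were dropped
        assert fit.trail[0] == "dropped random-effect correlations"

    def test_requires_multiple_participants(self, rng):
        scores = _score_table(rng, 1, 4, {"intercept": 1.0})
        with pytest.raises(EpochsError, match="participants"):
            fit_mixed(scores)

    def test_label_permutation_type_I_error(self, rng):
        """Permuting condition labels within participants nulls every fixed
        effect; the magnitude term's nominal .05 test should reject at
        chance rate (binomial tolerance at 200 refits)."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            scores = _score_table(
                rng, 10, 3, {"intercept": 2.0},
                subj_sd={"intercept": 1.0, "beneficiary": 0.4,
                         "magnitude": 0.4, "time": 0.4},
                noise_sd=2.0)
            # permute trial labels within participant
            for pid, g in scores.groupby("participant"):
                perm = rng.permutation(len(g))
                cols = dz.conditions_frame(
                    np.tile(np.repeat(np.arange(8), 3), 1)).iloc[perm]
                scores.loc[g.index, cols.columns] = cols.to_numpy()
            fit = fit_mixed(scores)
            p = fit.table.set_index("term").loc["magnitude", "p"]
            hits += p < 0.05
        assert hits / n_rep <= 0.075


def _hand_fit(betas, cov=None):
    beta = np.array([betas.get(t, 0.0) for t in dz.TERMS])
    table = pd.DataFrame({"term": list(dz.TERMS), "beta": beta,
                          "se": 1.0, "stat": beta, "p": 1.0})
    return MixedFitResult(table=table, trail=[], converged=True,
                          cov_fixed=cov if cov is not None else np.eye(8))


class TestEmmContrasts:
    def test_no_interactions_gives_identical_simple_effects(self):
        fit = _hand_fit({"magnitude": 2.0})
        tab = emm_contrasts(fit, "simple_magnitude")
        np.testing.assert_allclose(tab["estimate"], 2.0)

    def test_sign_bookkeeping_by_hand(self):
        """beta_mag = 2, beta_3way = 1: the simple magnitude effect in cell
        (b, t) is 2 + b*t (signs worked out by hand)."""
        fit = _hand_fit({"magnitude": 2.0, "beneficiary:magnitude:time": 1.0})
        tab = emm_contrasts(fit, "simple_magnitude").set_index("contrast")
        assert tab.loc["magnitude | self, immediate", "estimate"] == \
            pytest.approx(2.0 + (-0.5) * (-0.5))
        assert tab.loc["magnitude | self, delayed", "estimate"] == \
            pytest.approx(2.0 + (-0.5) * (0.5))
        assert tab.loc["magnitude | other, immediate", "estimate"] == \
            pytest.approx(2.0 + (0.5) * (-0.5))
        assert tab.loc["magnitude | other, delayed", "estimate"] == \
            pytest.approx(2.0 + (0.5) * (0.5))

    def test_interaction_within_time_levels(self):
        fit = _hand_fit({"beneficiary:magnitude": -1.0,
                         "beneficiary:magnitude:time": 2.0})
        tab = emm_contrasts(fit, "ben_by_mag_within_time").set_index("contrast")
        assert tab.loc["beneficiary:magnitude | immediate", "estimate"] == \
            pytest.approx(-1.0 - 1.0)
        assert tab.loc["beneficiary:magnitude | delayed", "estimate"] == \
            pytest.approx(-1.0 + 1.0)

    def test_unknown_family(self):
        with pytest.raises(EpochsError, match="family"):
            emm_contrasts(_hand_fit({}), "nonsense")


class TestFdr:
    @staticmethod
    def _brute_force_bh(p):
        """Independent step-up oracle: adjusted p = min over j>=rank of
        m*p_(j)/j, computed by direct scan."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            adj[i] = running
        return adj

    def test_worked_example(self):
        got = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_bh(p), self._brute_force_bh(p),
                                       atol=1e-12)


def _ratings_frame(Y):
    """participants × 8 cells (canonical order) -> tidy rating table."""
    tab = dz.cell_table()
    rows = []
    for s in range(Y.shape[0]):
        t = tab.copy()
        t["participant"] = f"p{s:02d}"
        t["rating"] = Y[s]
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _brute_force_anova_F(Y, term_idx):
    """Sums-of-squares oracle for one term of the 2x2x2 within design."""
    n = Y.shape[0]
    w = dz.design_matrix()[:, term_idx]
    c = Y @ w                       # participant-level contrast values
    # SS decomposition for a 1-df within contrast
    ss_effect = n * c.mean() ** 2
    ss_error = ((c - c.mean()) ** 2).sum()
    return (ss_effect / 1) / (ss_error / (n - 1))


class TestRmAnova:
    def test_equals_sums_of_squares_oracle(self, rng):
        Y = rng.normal(5, 1.5, size=(12, 8))
        res = rm_anova(_ratings_frame(Y))
        for _, row in res.table.iterrows():
            k = dz.TERMS.index(row["term"])
            F_oracle = _brute_force_anova_F(Y, k)
            assert row["F"] == pytest.approx(F_oracle, rel=1e-10)
            assert row["df1"] == 1 and row["df2"] == 11
            assert row["eta_p2"] == pytest.approx(
                row["F"] / (row["F"] + 11), rel=1e-10)

    def test_paired_t_equivalence(self, rng):
        Y = rng.normal(5, 1.0, size=(15, 8))
        res = rm_anova(_ratings_frame(Y)).table.set_index("term")
        large = Y[:, dz.cell_table()["magnitude"].to_numpy() == "large"]
        small = Y[:, dz.cell_table()["magnitude"].to_numpy() == "small"]
        t, p = scipy.stats.ttest_rel(large.mean(axis=1), small.mean(axis=1))
        assert res.loc["magnitude", "F"] == pytest.approx(t ** 2, rel=1e-10)
        assert res.loc["magnitude", "p"] == pytest.approx(p, rel=1e-10)

    def test_degenerate_constant_contrast_flagged(self):
        Y = np.zeros((6, 8))
        mag = dz.cell_table()["magnitude"].to_numpy() == "large"
        Y[:, mag] = 2.0                # identical nonzero effect everywhere
        Y += np.arange(6)[:, None] * 0.0
        res = rm_anova(_ratings_frame(Y))
        row = res.table.set_index("term").loc["magnitude"]
        assert np.isinf(row["F"])
        assert "magnitude" in res.degenerate_terms

    def test_null_type_I_near_nominal(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            Y = rng.normal(5, 1, size=(10, 8))
            res = rm_anova(_ratings_frame(Y)).table.set_index("term")
            hits += res.loc["beneficiary", "p"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)

    def test_missing_cells_error(self, rng):
        tab = _ratings_frame(rng.normal(size=(4, 8)))
        with pytest.raises(EpochsError):
            rm_anova(tab.iloc[:-1])


def _corr_scores(rng, effects_by_cell):
    """Build a minimal score table whose per-participant magnitude effects
    equal the given values; effects_by_cell: (n_sub, 2 ben, 2 time)."""
    n_sub = effects_by_cell.shape[0]
    rows = []
    cells = np.repeat(np.arange(8), 2)
    tab0 = dz.conditions_frame(cells)
    for s in range(n_sub):
        vals = np.zeros(len(cells))
        for i, row in tab0.iterrows():
            ib = dz.LEVELS["beneficiary"].index(row["beneficiary"])
            it = dz.LEVELS["time"].index(row["time"])
            if row["magnitude"] == "large":
                vals[i] = effects_by_cell[s, ib, it]
        t = tab0.copy()
        t["participant"] = f"p{s:02d}"
        t["value"] = vals
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


class TestMagnitudeEffectCorrelations:
    def test_identical_effects_give_r_one_and_zero_comparison(self, rng):
        base = rng.normal(2, 1, size=(20, 1, 2))
        eff = np.repeat(base, 2, axis=1)      # self effect == other effect
        out = magnitude_effect_correlations({"rewp": _corr_scores(rng, eff)})
        c = out[0]
        assert c.r_immediate == pytest.approx(1.0)
        assert c.r_delayed == pytest.approx(1.0)
        assert c.z_comparison == pytest.approx(0.0, abs=1e-9)

    def test_independent_effects_give_r_near_zero(self, rng):
        eff = rng.normal(0, 1, size=(400, 2, 2))
        out = magnitude_effect_correlations({"p3": _corr_scores(rng, eff)})
        assert abs(out[0].r_immediate) < 0.15
        assert abs(out[0].r_delayed) < 0.15

    def test_bivariate_rho_half_recovered_in_simulation(self, rng):
        """Simulation oracle: effects drawn bivariate-normal with rho = 0.5
        at n = 40; the mean Pearson r over replicates approaches 0.5."""
        rho, n_sub, n_rep = 0.5, 40, 300
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        rs = []
        for _ in range(n_rep):
            z = rng.standard_normal((n_sub, 2, 2))
            eff = np.einsum("ij,sjt->sit", L, z)
            out = magnitude_effect_correlations(
                {"m": _corr_scores(rng, eff)})
            rs += [out[0].r_immediate, out[0].r_delayed]
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_fdr_family_spans_measures_and_levels(self, rng):
        eff = rng.normal(0, 1, size=(15, 2, 2))
        out = magnitude_effect_correlations({
            "a": _corr_scores(rng, eff),
            "b": _corr_scores(rng, rng.normal(0, 1, size=(15, 2, 2)))})
        praw = [p for c in out for p in (c.p_immediate, c.p_delayed)]
        padj = [p for c in out for p in (c.p_immediate_fdr, c.p_delayed_fdr)]
        np.testing.assert_allclose(padj, fdr_bh(praw))
        assert all(a >= r - 1e-12 for a, r in zip(padj, praw))

    def test_too_few_participants(self, rng):
        eff = rng.normal(size=(2, 2, 2))
        with pytest.raises(EpochsError, match="participants"):
            magnitude_effect_correlations({"x": _corr_scores(rng, eff)})
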