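"""Model/neural RDMs, RDM regression, cluster permutation inference."""

import numpy as np
import pytest
import scipy.stats

from prosorew import design as dz
from prosorew import rsa
from prosorew.epochs import EpochsError
from prosorew.rsa import (ClusterResult, ModelRDM, NeuralRDMSeries,
                          cluster_permutation, model_rdms, neural_rdm,
                          rdm_regression)

from conftest import toy_epochs


def _zs(v):
    return (v - v.mean()) / v.std()


class TestModelRDMs:
    def test_structure(self):
        rdms = model_rdms()
        assert set(rdms) == {"beneficiary", "magnitude", "time"}
        for m in rdms.values():
            M = m.matrix
            assert M.shape == (8, 8)
            np.testing.assert_array_equal(M, M.T)
            np.testing.assert_array_equal(np.diag(M), 0)
            assert set(np.unique(M)) == {0.0, 1.0}
            assert m.upper().sum() == 16  # 16 of 28 upper-triangle entries

    def test_model_pair_correlation_is_exactly_minus_one_sixth(self):
        """The z-scored upper-triangle vectors of two binary factor RDMs are
        not orthogonal: each pair correlates at exactly -1/6 (16 differing
        pairs per factor, 8 jointly differing, out of 28).  Coefficients are
        nevertheless identified exactly because the vectors are linearly
        independent."""
        rdms = model_rdms()
        vs = [_zs(m.upper()) for m in rdms.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.dot(vs[i], vs[j]) / 28
                assert r == pytest.approx(-1.0 / 6.0, abs=1e-12)

    def test_full_matrix_vectorization_is_orthogonal(self):
        """Orthogonality does hold when the whole 8x8 matrix (diagonal and
        both triangles) is vectorized - the asymmetry comes purely from
        keeping only the upper triangle."""
        rdms = model_rdms()
        vs = [m.matrix.ravel() for m in rdms.values()]
        vs = [(v - v.mean()) for v in vs]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.dot(vs[i], vs[j]) == pytest.approx(0.0, abs=1e-10)


class TestNeuralRDM:
    def _epochs_with_cell_means(self, means, noise_sd=0.5, n_per_cell=4,
                                n_t=20, rng=None):
        """means: (8, n_ch) topographies, constant over time."""
        rng = rng or np.random.default_rng(0)
        n_cells, n_ch = means.shape
        cells = np.repeat(np.arange(n_cells), n_per_cell)
        data = means[cells][:, :, None] + rng.normal(
            0, noise_sd, (cells.size, n_ch, n_t))
        return toy_epochs(data, cells=cells)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        means = rng.normal(size=(8, 5))
        e = self._epochs_with_cell_means(means, rng=rng)
        n = neural_rdm(e, channels=e.channels, cov=np.eye(5))
        # noiseless part: compare time-averaged distances to direct norms
        d_avg = n.dist.mean(axis=0)
        for i in range(8):
            for j in range(8):
                expected = np.linalg.norm(means[i] - means[j])
                assert d_avg[i, j] == pytest.approx(expected, abs=0.6)

    def test_hand_computed_quadratic_form_three_channels(self):
        """3-channel toy with an explicit covariance: the distance matches
        the hand-evaluated quadratic form to 1e-10."""
        means = np.zeros((8, 3))
        means[0] = [1.0, 2.0, 3.0]
        means[1] = [0.0, 1.0, 5.0]
        e = self._epochs_with_cell_means(means, noise_sd=0.1, n_t=1)
        cov = np.array([[2.0, 0.5, 0.0],
                        [0.5, 1.0, 0.2],
                        [0.0, 0.2, 1.5]])
        n = neural_rdm(e, channels=e.channels, cov=cov)
        # hand computation of sqrt(d' Σ^{-1} d) on the *realized* cell means
        m0 = e.data[e.conditions.index < 4].mean(axis=(0, 2))  # not used
        cellmeans = []
        for c in range(8):
            mask = (np.arange(e.n_trials) // 4) == c
            cellmeans.append(e.data[mask].mean(axis=(0, 2)))
        d = cellmeans[0] - cellmeans[1]
        expected = float(np.sqrt(d @ np.linalg.inv(cov) @ d))
        assert n.dist[0, 0, 1] == pytest.approx(expected, abs=1e-10)

    def test_identical_cell_means_give_zero_distance(self):
        means = np.zeros((8, 4))
        means[2] = means[5] = [1.0, -1.0, 2.0, 0.5]
        e = self._epochs_with_cell_means(means, noise_sd=0.0, n_t=5)
        e.data += 0.0
        n = neural_rdm(e, channels=e.channels, cov=np.eye(4))
        assert n.dist[0, 2, 5] == pytest.approx(0.0, abs=1e-12)

    def test_common_topography_shift_leaves_rdm_unchanged(self, rng):
        means = rng.normal(size=(8, 4))
        e1 = self._epochs_with_cell_means(means, rng=np.random.default_rng(5))
        common = rng.normal(size=4)
        e2 = self._epochs_with_cell_means(means + common,
                                          rng=np.random.default_rng(5))
        n1 = neural_rdm(e1, channels=e1.channels, cov=np.eye(4))
        n2 = neural_rdm(e2, channels=e2.channels, cov=np.eye(4))
        np.testing.assert_allclose(n1.dist, n2.dist, atol=1e-8)

    def test_singular_covariance_advises_shrinkage(self):
        means = np.zeros((8, 3))
        e = self._epochs_with_cell_means(means, noise_sd=0.5, n_t=4)
        e.data[:, 2, :] = e.data[:, 1, :]        # duplicated channel
        with pytest.raises(EpochsError, match="shrinkage"):
            neural_rdm(e, channels=e.channels, shrinkage=0.0)

    def test_too_few_trials_per_cell(self):
        e = toy_epochs(np.zeros((8, 2, 10)))     # one trial per cell
        with pytest.raises(EpochsError, match="fewer than 2"):
            neural_rdm(e, channels=e.channels, cov=np.eye(2))


def _series_from_vector(vec, n_t=5):
    """Wrap a 28-entry upper-triangle vector into a NeuralRDMSeries."""
    M = np.zeros((8, 8))
    iu = np.triu_indices(8, k=1)
    M[iu] = vec
    M += M.T
    dist = np.tile(M, (n_t, 1, 1))
    return NeuralRDMSeries(dist=dist, times=np.arange(n_t, dtype=float) * 4,
                           cells=dz.cell_table())


class TestRDMRegression:
    def test_self_regression_recovers_unit_coefficient(self):
        models = model_rdms()
        n = _series_from_vector(models["magnitude"].upper())
        c = rdm_regression(n, models)
        k = c.predictors.index("magnitude")
        np.testing.assert_allclose(c.coef[k], 1.0, atol=1e-10)
        for j, name in enumerate(c.predictors):
            if name != "magnitude":
                np.testing.assert_allclose(c.coef[j], 0.0, atol=1e-10)

    def test_mixture_recovers_weights(self):
        models = model_rdms()
        mix = (0.5 * _zs(models["beneficiary"].upper())
               + 0.25 * _zs(models["time"].upper()))
        # regression is on the z-scored neural vector, so weights are
        # recovered up to the overall scale of the mixture
        n = _series_from_vector(mix)
        c = rdm_regression(n, models)
        scale = mix.std()
        got = {name: c.coef[i, 0] for i, name in enumerate(c.predictors)}
        assert got["beneficiary"] == pytest.approx(0.5 / scale, abs=1e-10)
        assert got["time"] == pytest.approx(0.25 / scale, abs=1e-10)
        assert got["magnitude"] == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_coefficients_average_near_zero(self, rng):
        models = model_rdms()
        coefs = []
        for _ in range(50):
            n = _series_from_vector(rng.normal(size=28), n_t=1)
            c = rdm_regression(n, models)
            coefs.append(c.coef[:, 0])
        m = np.mean(coefs, axis=0)
        assert np.all(np.abs(m) < 0.1)

    def test_collinear_models_error_names_pair(self):
        models = model_rdms()
        dup = ModelRDM(name="copy", matrix=models["time"].matrix.copy())
        with pytest.raises(EpochsError, match="time.*copy|copy.*time"):
            rdm_regression(_series_from_vector(np.random.default_rng(0)
                                               .normal(size=28)),
                           {"time": models["time"], "copy": dup})


class TestClusterPermutation:
    def _null_coefs(self, rng, n_sub=20, n_t=60):
        return rng.normal(0, 1.0, (n_sub, n_t))

    def test_sign_flip_symmetry(self, rng):
        coefs = self._null_coefs(rng) + 0.8
        times = np.arange(60, dtype=float) * 4
        r1 = cluster_permutation(coefs, times, n_perm=500, seed=3)
        r2 = cluster_permutation(-coefs, times, n_perm=500, seed=3)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(-c.mass for c in r2.clusters)
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(
            sorted(c.p for c in r1.clusters), sorted(c.p for c in r2.clusters))

    def test_boxcar_effect_detected_with_high_power(self, rng):
        """A participant-consistent 6-SD boxcar over 200 ms yields a cluster
        covering >= 80% of the boxcar at p <= 0.002."""
        n_sub, n_t = 20, 150
        dt = 4.0
        times = np.arange(n_t) * dt
        coefs = rng.normal(0, 1.0, (n_sub, n_t))
        box = (times >= 200) & (times < 400)        # 50 samples = 200 ms
        coefs[:, box] += 6.0
        res = cluster_permutation(coefs, times, n_perm=1000, seed=1)
        sig = res.significant(0.05)
        assert sig
        best = max(sig, key=lambda c: abs(c.mass))
        assert best.p <= 0.002
        inside = (times >= best.start_ms) & (times <= best.end_ms) & box
        assert inside.sum() >= 0.8 * box.sum()

    def test_no_suprathreshold_returns_empty_list(self):
        coefs = np.full((10, 20), 0.001)
        coefs += np.random.default_rng(0).normal(0, 1e-6, coefs.shape)
        res = cluster_permutation(coefs, np.arange(20.0), n_perm=500, seed=0)
        assert isinstance(res, ClusterResult)

    def test_agrees_with_mne_reference(self, rng):
        """Cross-check cluster extents and p-values against the established
        implementation in MNE on the same data."""
        from mne.stats import permutation_cluster_1samp_test

        n_sub, n_t = 16, 80
        coefs = rng.normal(0, 1.0, (n_sub, n_t))
        coefs[:, 30:50] += 1.2
        times = np.arange(n_t, dtype=float)
        thr = scipy.stats.t.ppf(0.975, n_sub - 1)
        ours = cluster_permutation(coefs, times, n_perm=2000, seed=0)
        t_obs, clusters, pvals, _ = permutation_cluster_1samp_test(
            coefs, threshold=thr, n_permutations=2000, tail=0, seed=1,
            out_type="indices", verbose="error")
        mne_sets = {(int(idx[0][0]), int(idx[0][-1])) for idx in clusters}
        our_sets = {(int(c.start_ms), int(c.end_ms)) for c in ours.clusters}
        assert our_sets == mne_sets
        # p-values of the dominant cluster agree to Monte-Carlo precision
        p_mne = min(pvals)
        p_ours = min(c.p for c in ours.clusters)
        assert abs(p_ours - p_mne) < 0.02

    def test_requires_enough_participants_and_permutations(self, rng):
        with pytest.raises(EpochsError, match="participants"):
            cluster_permutation(rng.normal(size=(4, 10)), np.arange(10.0),
                                n_perm=500, seed=0)
        with pytest.raises(EpochsError, match="permutations"):
            cluster_permutation(rng.normal(size=(10, 10)), np.arange(10.0),
                                n_perm=100, seed=0)


class TestSplitDesign:
    def test_split_models_have_6_entries_and_minus_half_correlation(self):
        cells = dz.cell_table().query("time == 'immediate'").drop_duplicates(
            subset=["beneficiary", "magnitude"]).reset_index(drop=True)
        rdms = model_rdms(("beneficiary", "magnitude"), cells)
        a = _zs(rdms["beneficiary"].upper())
        b = _zs(rdms["magnitude"].upper())
        assert a.size == 6
        # 2 of 6 pairs differ on both factors: correlation is exactly -1/2
        assert np.dot(a, b) / 6 == pytest.approx(-0.5, abs=1e-12)

    def test_identical_data_in_both_levels_identical_series(self, rng):
        # build epochs where each (beneficiary, magnitude) pattern repeats
        # identically across time levels
        patterns = rng.normal(size=(4, 6))
        cells = np.repeat(np.arange(8), 3)
        bm = (cells // 4) * 2 + (cells // 2) % 2   # beneficiary x magnitude id
        data = patterns[bm][:, :, None] + rng.normal(
            0, 0.01, (cells.size, 6, 8))
        # make noise identical across the two time levels per (bm, repeat)
        e = toy_epochs(data, cells=cells)
        # overwrite: time level is cells % 2; force exact duplication
        src = {}
        for tr, c in enumerate(cells):
            if c % 2 == 0:
                src[(bm[tr], tr % 3)] = e.data[tr]
        for tr, c in enumerate(cells):
            if c % 2 == 1:
                e.data[tr] = src[(bm[tr], tr % 3)]
        out = rsa.rsa_by_time_condition([e], channels=e.channels,
                                        shrinkage=0.5)
        np.testing.assert_allclose(out["immediate"]["magnitude"],
                                   out["delayed"]["magnitude"], atol=1e-8)
        np.testing.assert_allclose(out["immediate"]["beneficiary"],
                                   out["delayed"]["beneficiary"], atol=1e-8)
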