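"""z-scoring, SVD PCA, phase-scrambled surrogates, parallel analysis, and
the Gaussian KL decision rule."""

import numpy as np
import pytest

from widedecode.bootstrap import BootstrapConfig
from widedecode.pca_kl import (
    GaussianSummary,
    gaussian_kl,
    kl_classify,
    parallel_analysis,
    pca_svd,
    phase_scramble,
    principal_angles,
    replicate_accuracy_correlation,
    summarize_gaussian,
    zscore_columns,
)
from widedecode.synthetic import MapStudyConfig, gen_map_study


class TestZscore:
    def test_columns_standardized(self, rng):
        x = rng.normal(3, 2, size=(15, 40))
        z = zscore_columns(x)
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0)

    def test_constant_column_zeroed(self):
        x = np.column_stack([np.full(6, 3.0), np.arange(6.0)])
        z = zscore_columns(x)
        assert np.all(z[:, 0] == 0)

    def test_round_trip(self, rng):
        x = rng.normal(size=(10, 20))
        z, means, sds = zscore_columns(x, return_record=True)
        assert np.allclose(z * sds + means, x, atol=1e-10)


class TestPcaSvd:
    def test_rank_one_dominates(self, rng):
        x = np.outer(rng.normal(size=12), rng.normal(size=50))
        x += 1e-6 * rng.normal(size=x.shape)
        space = pca_svd(x)
        assert space.explained_variance_ratio[0] > 0.999

    def test_loadings_orthonormal_and_ev_sorted(self, rng):
        space = pca_svd(rng.normal(size=(15, 60)))
        k = space.loadings.shape[1]
        assert np.allclose(space.loadings.T @ space.loadings, np.eye(k), atol=1e-8)
        assert np.all(np.diff(space.explained_variance) <= 1e-10)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(size=(10, 30))
        l1 = pca_svd(x).loadings
        l2 = pca_svd(x.copy()).loadings
        assert np.array_equal(l1, l2)
        maxidx = np.abs(l1).argmax(axis=0)
        assert np.all(l1[maxidx, np.arange(l1.shape[1])] > 0)

    def test_latent_subspace_recovered(self, latent_study):
        space = pca_svd(latent_study.maps_interest.values)
        sds = np.where(space.column_sds > 0, space.column_sds, 1.0)
        scaled_truth = latent_study.truth.loadings / sds[:, None]
        angles = principal_angles(space.loadings[:, :3], scaled_truth)
        assert np.all(angles < 10.0)


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.normal(size=(5, 128))
        sur = phase_scramble(x, rng=1)
        for row, srow in zip(x, sur):
            assert np.allclose(np.abs(np.fft.rfft(row)), np.abs(np.fft.rfft(srow)),
                               rtol=1e-8, atol=1e-10)

    def test_mean_preserved_odd_and_even_lengths(self, rng):
        for n in (64, 65):
            x = rng.normal(2.0, 1.0, size=n)
            sur = phase_scramble(x, rng=2)
            assert sur.mean() == pytest.approx(x.mean(), abs=1e-10)

    def test_autocorrelation_approximately_preserved(self):
        # smooth map: surrogate keeps its lag-1 autocorrelation on average
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(3)
        x = gaussian_filter1d(rng.normal(size=512), sigma=4, mode="wrap")

        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]

        diffs = [abs(lag1(phase_scramble(x, rng=seed)) - lag1(x)) for seed in range(100)]
        assert np.mean(diffs) < 0.1

    def test_grid_mode_preserves_3d_spectrum(self, rng):
        shape = (6, 5, 4)
        x = rng.normal(size=int(np.prod(shape)))
        sur = phase_scramble(x, rng=4, grid_shape=shape)
        f_x = np.abs(np.fft.fftn(x.reshape(shape)))
        f_s = np.abs(np.fft.fftn(sur.reshape(shape)))
        assert np.allclose(f_x, f_s, rtol=1e-8, atol=1e-8)
        assert sur.mean() == pytest.approx(x.mean(), abs=1e-10)

    def test_destroys_cross_map_covariance(self, rng):
        shared = rng.normal(size=200)
        x = shared[None, :] + 0.1 * rng.normal(size=(20, 200))
        sur = phase_scramble(x, rng=5)
        corr_orig = np.corrcoef(x)[np.triu_indices(20, 1)].mean()
        corr_sur = np.corrcoef(sur)[np.triu_indices(20, 1)].mean()
        assert corr_orig > 0.9
        assert abs(corr_sur) < 0.2


class TestParallelAnalysis:
    def test_pure_noise_yields_zero(self, rng):
        x = rng.normal(size=(20, 300))
        k, ens = parallel_analysis(x, n_surrogates=60, seed=9)
        assert k == 0
        assert ens.spectra.shape == (60, 20)

    def test_latent_rank_recovered(self, latent_study):
        k, _ = parallel_analysis(latent_study.maps_interest.values,
                                 n_surrogates=100, seed=10)
        assert k == 3

    def test_invariant_to_subject_relabeling(self, rng):
        x = rng.normal(size=(15, 100)) + np.outer(rng.normal(size=15), rng.normal(size=100))
        k1, _ = parallel_analysis(x, n_surrogates=40, seed=11)
        k2, _ = parallel_analysis(x[::-1], n_surrogates=40, seed=11)
        assert k1 == k2


class TestGaussianKl:
    def test_identical_summaries_zero(self, rng):
        s = summarize_gaussian(rng.normal(size=(30, 3)))
        assert gaussian_kl(s, s) == pytest.approx(0.0, abs=1e-10)

    def test_univariate_closed_form(self):
        test = GaussianSummary(mu=np.array([0.0]), sigma=np.array([[1.0]]))
        train = GaussianSummary(mu=np.array([1.0]), sigma=np.array([[2.0]]))
        expected = 0.5 * (0.5 - 1 + 0.5 + np.log(2))
        assert gaussian_kl(test, train) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.34657, abs=1e-5)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(12)
        k = 3
        a = rng.normal(size=(k, k))
        sig_test = a @ a.T + np.eye(k)
        b = rng.normal(size=(k, k))
        sig_train = b @ b.T + np.eye(k)
        mu_test, mu_train = rng.normal(size=(2, k))
        test = GaussianSummary(mu=mu_test, sigma=sig_test)
        train = GaussianSummary(mu=mu_train, sigma=sig_train)
        kl = gaussian_kl(test, train)
        # E_test[log p_test - log p_train] by direct sampling
        n = 10**6
        draws = rng.multivariate_normal(mu_test, sig_test, size=n)
        from scipy.stats import multivariate_normal

        logs = (multivariate_normal.logpdf(draws, mu_test, sig_test)
                - multivariate_normal.logpdf(draws, mu_train, sig_train))
        mc, se = logs.mean(), logs.std(ddof=1) / np.sqrt(n)
        assert abs(kl - mc) < 3 * se

    def test_nonnegative_and_linear_invariance(self, rng):
        for _ in range(10):
            x = rng.normal(size=(40, 3))
            y = rng.normal(size=(40, 3)) + rng.normal(size=3)
            s1, s2 = summarize_gaussian(x), summarize_gaussian(y)
            kl = gaussian_kl(s1, s2)
            assert kl >= -1e-10
            # common invertible linear map leaves KL unchanged
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            t1 = summarize_gaussian(x @ A.T)
            t2 = summarize_gaussian(y @ A.T)
            assert gaussian_kl(t1, t2) == pytest.approx(kl, rel=1e-6, abs=1e-8)

    def test_dimension_mismatch(self):
        a = GaussianSummary(np.zeros(2), np.eye(2))
        b = GaussianSummary(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            gaussian_kl(a, b)


class TestKlClassify:
    def test_latent_structure_pc_beats_univariate(self):
        # condition-specific across-subject covariance with a tiny mean
        # effect: the component-space decoder wins over the whole-mask
        # signed-t reference
        pcs, uts = [], []
        for s in range(4):
            study = gen_map_study(MapStudyConfig(
                n_subjects=50, n_voxels=1000, signal_profile="widespread",
                effect_scale=0.02, latent_rank=4, latent_strength=0.2, seed=900 + s,
            ))
            cfg = BootstrapConfig(n_replicates=40, seed=950 + s)
            pc = kl_classify(study, k=4, config=cfg, mode="pc_space")
            ut = kl_classify(study, k=4, config=cfg, mode="univariate_t")
            pcs.append(pc.theta_632plus[0])
            uts.append(ut.theta_632plus[0])
            # replicate series from the same seed are comparable
            assert np.isfinite(replicate_accuracy_correlation(pc, ut))
        assert np.mean(pcs) > np.mean(uts)
        assert np.mean(pcs) > 0.9

    def test_null_study_near_chance_on_average(self):
        accs = []
        for s in range(10):
            study = gen_map_study(MapStudyConfig(
                n_subjects=24, n_voxels=300, signal_profile="null", seed=700 + s
            ))
            res = kl_classify(study, k=3, config=BootstrapConfig(n_replicates=40, seed=750 + s))
            accs.append(res.theta_632plus[0])
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_needs_enough_subjects(self, rng):
        study = gen_map_study(MapStudyConfig(n_subjects=6, n_voxels=50, seed=1))
        with pytest.raises(ValueError, match=">= 8"):
            kl_classify(study, k=2)
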