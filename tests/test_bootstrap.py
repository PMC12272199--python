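"""Mann-Whitney AUC, the floor-free 0.632+ estimator, nested covariance,
and covariate orthogonalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from widedecode.bootstrap import (
    BootstrapConfig,
    auc_columns,
    bootstrap_632plus,
    combine_632plus,
    evaluate_apparent,
    mann_whitney_auc,
    nested_bootstrap_cov,
    residualize_paired_scores,
    residualize_scores,
)
from widedecode.synthetic import MapStudyConfig, gen_map_study


def brute_force_auc(a, b):
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return wins / (len(a) * len(b))


class TestMannWhitneyAuc:
    def test_derived_example(self):
        est = mann_whitney_auc([3, 1, 2], [0, 1.5, 2.5])
        assert est.auc == pytest.approx(6 / 9)

    def test_boundaries(self):
        assert mann_whitney_auc([1, 1], [1, 1]).auc == 0.5
        assert mann_whitney_auc([5, 6], [1, 2]).auc == 1.0
        with pytest.raises(ValueError):
            mann_whitney_auc([], [1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 20, size=2)
        a = rng.integers(-3, 4, size=n1).astype(float)  # integers force ties
        b = rng.integers(-3, 4, size=n2).astype(float)
        assert mann_whitney_auc(a, b).auc == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    def test_complement_and_monotone_invariance(self, rng):
        a, b = rng.normal(size=(2, 15))
        auc = mann_whitney_auc(a, b).auc
        assert auc + mann_whitney_auc(b, a).auc == pytest.approx(1.0)
        assert mann_whitney_auc(np.exp(a), np.exp(b)).auc == pytest.approx(auc)

    def test_columnwise_agrees_with_scalar(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(9, 4))
        cols = auc_columns(a, b)
        for j in range(4):
            assert cols[j] == pytest.approx(mann_whitney_auc(a[:, j], b[:, j]).auc)


class TestCombine632Plus:
    def test_derived_formula_example(self):
        R, w, theta = combine_632plus(0.9, 0.7)
        assert R[0] == pytest.approx(0.5)
        assert w[0] == pytest.approx(0.632 / 0.816, abs=1e-5)
        assert theta[0] == pytest.approx(0.74510, abs=1e-4)

    def test_fixed_point(self):
        R, w, theta = combine_632plus(0.8, 0.8)
        assert R[0] == 0.0
        assert w[0] == pytest.approx(0.632)
        assert theta[0] == pytest.approx(0.8)

    def test_floor_free_below_chance(self):
        # oob <= 0.5 -> full weight on oob, estimate allowed below 0.5
        R, w, theta = combine_632plus(0.9, 0.45)
        assert R[0] == 1.0
        assert w[0] == pytest.approx(1.0)
        assert theta[0] == pytest.approx(0.45)

    def test_rate_clamped(self):
        # apparent below chance but oob above: rate pins at 0
        R, w, theta = combine_632plus(0.4, 0.6)
        assert R[0] == 0.0
        assert theta[0] == pytest.approx((1 - 0.632) * 0.4 + 0.632 * 0.6)


class TestBootstrap632Plus:
    def test_duplicated_conditions_all_chance(self, rng):
        x = rng.normal(size=(12, 100))
        from widedecode.decoders import ActivationMapStack
        from widedecode.synthetic import MapStudy, MapStudyTruth

        study = MapStudy(
            maps_interest=ActivationMapStack(x.copy()),
            maps_nointerest=ActivationMapStack(x.copy()),
            truth=MapStudyTruth(np.zeros(100), np.zeros((100, 0)), np.zeros((12, 0))),
        )
        assert np.allclose(evaluate_apparent(study, n_bins=5), 0.5)

    def test_apparent_auc_shows_selection_bias_on_null(self, null_study):
        # trained and tested on the same sample, the top bin overfits
        app = evaluate_apparent(null_study, n_bins=10)
        assert app[-1] > 0.55

    def test_reproducible_given_seed(self, null_study):
        cfg = BootstrapConfig(n_replicates=10, seed=5)
        r1 = bootstrap_632plus(null_study, cfg)
        r2 = bootstrap_632plus(null_study, cfg)
        assert np.array_equal(r1.replicates, r2.replicates)
        assert np.array_equal(r1.theta_632plus, r2.theta_632plus)
        r3 = bootstrap_632plus(null_study, BootstrapConfig(n_replicates=10, seed=6))
        assert not np.array_equal(r1.replicates, r3.replicates)

    def test_invariants_of_result(self, widespread_study, quick_bootstrap):
        res = bootstrap_632plus(widespread_study, quick_bootstrap)
        assert np.all((res.R_hat >= 0) & (res.R_hat <= 1))
        assert np.all((res.w_hat >= 0.632 - 1e-12) & (res.w_hat <= 1 + 1e-12))
        assert np.allclose(
            res.theta_632plus,
            (1 - res.w_hat) * res.theta_app + res.w_hat * res.theta_boot,
        )

    def test_widespread_all_bins_above_chance(self, widespread_study, quick_bootstrap):
        res = bootstrap_632plus(widespread_study, quick_bootstrap)
        assert np.all(res.theta_632plus > 0.5)

    def test_small_sample_rejected(self):
        study = gen_map_study(MapStudyConfig(n_subjects=3, n_voxels=50, seed=0))
        with pytest.raises(ValueError, match=">= 4 subjects"):
            bootstrap_632plus(study, BootstrapConfig(n_replicates=5, seed=0))


class TestNestedBootstrapCov:
    def test_covariance_symmetric_psd_and_shapes(self, null_study):
        cfg = BootstrapConfig(outer_replicates=25, inner_replicates=15, seed=3)
        cov = nested_bootstrap_cov(null_study, cfg, n_bins=5)
        assert cov.replicates.shape == (25, 5)
        assert cov.covariance.shape == (5, 5)
        assert np.allclose(cov.covariance, cov.covariance.T)
        assert np.linalg.eigvalsh(cov.covariance).min() >= -1e-10

    def test_variance_shrinks_with_more_subjects(self):
        # Monte-Carlo over seeds: doubling n halves-ish the outer-loop
        # spread of each bin's estimate
        def mean_outer_var(n_subjects, seeds):
            out = []
            for s in seeds:
                study = gen_map_study(MapStudyConfig(
                    n_subjects=n_subjects, n_voxels=200,
                    signal_profile="widespread", seed=1000 + s))
                cfg = BootstrapConfig(outer_replicates=15, inner_replicates=10,
                                      seed=2000 + s)
                cov = nested_bootstrap_cov(study, cfg, n_bins=4)
                out.append(np.diag(cov.covariance).mean())
            return np.mean(out)

        seeds = range(10)
        assert mean_outer_var(32, seeds) < mean_outer_var(16, seeds)

    def test_transform_applied(self, null_study):
        cfg = BootstrapConfig(outer_replicates=10, inner_replicates=10, seed=3)
        raw = nested_bootstrap_cov(null_study, cfg, n_bins=4)
        doubled = nested_bootstrap_cov(null_study, cfg, n_bins=4, transform=lambda v: 2 * v)
        assert np.allclose(doubled.replicates, 2 * raw.replicates)
        assert np.allclose(doubled.covariance, 4 * raw.covariance, atol=1e-12)


class TestResidualize:
    def test_orthogonal_covariate_only_centers(self, rng):
        y = rng.normal(size=(40, 3))
        y -= y.mean(axis=0)
        c = rng.normal(size=(40, 1))
        c -= c.mean()
        # project covariate out of y so they are exactly orthogonal
        y -= c @ (np.linalg.lstsq(c, y, rcond=None)[0])
        res = residualize_scores(y, c)
        assert np.allclose(res.scores, y, atol=1e-10)

    def test_scores_equal_covariate_vanish(self, rng):
        c = rng.normal(size=(20, 1))
        res = residualize_scores(np.hstack([c, 2 * c]), c)
        assert np.allclose(res.scores, 0, atol=1e-10)

    def test_rank_deficient_warns(self, rng):
        c = rng.normal(size=(15, 1))
        with pytest.warns(UserWarning, match="rank deficient"):
            residualize_scores(rng.normal(size=(15, 2)), np.hstack([c, c]))

    def test_confound_driven_auc_removed(self, rng):
        # separation exists only because the interest scans move more:
        # scores track per-scan motion, which differs between conditions
        m_i = rng.normal(1.0, 1.0, size=(40, 1))
        m_n = rng.normal(0.0, 1.0, size=(40, 1))
        interest = m_i + 0.1 * rng.normal(size=(40, 1))
        nointerest = m_n + 0.1 * rng.normal(size=(40, 1))
        _, _, delta = residualize_paired_scores(interest, nointerest, m_i, m_n)
        assert delta[0] > 0.1

    def test_motion_unrelated_signal_survives(self, rng):
        # genuine condition shift orthogonal to motion: joint
        # residualization must keep the separation
        m = rng.normal(size=(25, 1))
        noise = 0.1 * rng.normal(size=(25, 2, 1))
        interest = 2.0 + noise[:, 0]
        nointerest = noise[:, 1]
        res_i, res_n, delta = residualize_paired_scores(interest, nointerest, m, m)
        assert auc_columns(res_i, res_n)[0] == pytest.approx(1.0)
        assert abs(delta[0]) < 1e-9
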