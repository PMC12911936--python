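import numpy as np
import pandas as pd
import pytest

from gpmaps import (
    DeltaPrior,
    ObservedData,
    SequenceSpace,
    VCPrior,
    empirical_distance_correlation,
    estimate_replicate_variance,
    evaluate_predictions,
    fit_posterior,
    kernel_alignment_fit,
    mei,
    sample_vc_landscape,
)
from gpmaps.operators import DeltaPOperator, VCKernelOperator, \
    count_coefficients, projection_distance_profile
from gpmaps.simulate import lambdas_from_variance_fractions, make_observations


class TestReplicateVariance:
    def test_pooled_variance_hand_example(self):
        df = pd.DataFrame(
            {"sequence": ["A", "A", "B", "B", "B"],
             "y": [1.0, 1.2, 2.0, 2.4, 2.2]}
        )
        sigma2, table = estimate_replicate_variance(df)
        assert sigma2 == pytest.approx(0.1 / 3)
        by_seq = table.set_index("sequence")
        assert by_seq.loc["A", "var"] == pytest.approx(sigma2 / 2)
        assert by_seq.loc["B", "var"] == pytest.approx(sigma2 / 3)

    def test_identical_replicates_give_zero(self):
        df = pd.DataFrame({"sequence": ["A", "A"], "y": [1.0, 1.0]})
        sigma2, _ = estimate_replicate_variance(df)
        assert sigma2 == 0.0

    def test_no_replication_is_an_error(self):
        df = pd.DataFrame({"sequence": ["A", "B"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="replicates"):
            estimate_replicate_variance(df)


class TestDistanceCorrelation:
    def test_constant_y_gives_zero_covariances(self, dna2):
        data = ObservedData(dna2, [0, 1, 5, 9], np.full(4, 2.0))
        tab = empirical_distance_correlation(data)
        nz = tab["n_pairs"] > 0
        np.testing.assert_allclose(tab.loc[nz, "covariance"], 0.0, atol=1e-14)

    def test_additive_gp_covariance_is_linear_in_d(self):
        # exact additive function, fully observed, noiseless: c_d tracks
        # P_1(d) = alpha^-l [(alpha-1)(l-d) - d] up to the order-1 variance
        space = SequenceSpace("ACGT", 3)
        f = sample_vc_landscape(space, [0, 1, 0, 0], seed=5)
        data = ObservedData(space, np.arange(64), f.values)
        tab = empirical_distance_correlation(data)
        prof = projection_distance_profile(space, 1)
        ratio = tab["covariance"].values[1:] / prof[1:]
        # constant ratio across distance classes => same shape
        assert np.std(ratio) / np.mean(ratio) < 1e-6
        # zero crossing at d = l(alpha-1)/alpha = 2.25 sits between d=2 and 3
        assert tab["covariance"][2] > 0 > tab["covariance"][3]

    def test_two_observations_single_class(self, dna2):
        data = ObservedData(dna2, [0, 15], np.array([0.0, 1.0]))
        tab = empirical_distance_correlation(data)
        assert tab["n_pairs"][2] == 1
        assert tab["n_pairs"][1] == 0
        assert np.isnan(tab["covariance"][1])

    def test_noise_subtracted_at_zero(self, dna2, rng):
        y = rng.normal(size=8)
        idx = np.arange(8)
        noisy = ObservedData(dna2, idx, y, np.full(8, 0.5))
        clean = ObservedData(dna2, idx, y)
        t_noisy = empirical_distance_correlation(noisy)
        t_clean = empirical_distance_correlation(clean)
        assert t_noisy["covariance"][0] == pytest.approx(
            t_clean["covariance"][0] - 0.5
        )
        assert t_noisy["noise_corrected"][0]


class TestKernelAlignment:
    def test_exact_recovery_from_prior_profile(self):
        space = SequenceSpace("ACG", 4)
        lam_true = np.array([0.0, 2.0, 0.7, 0.0, 0.05])
        prof = VCKernelOperator(space, lam_true).distance_profile()
        tab = pd.DataFrame(
            {"d": np.arange(5), "covariance": prof,
             "n_pairs": np.full(5, 100), "noise_corrected": False}
        )
        lam_hat = kernel_alignment_fit(tab, space)
        np.testing.assert_allclose(lam_hat, lam_true, atol=1e-8)

    def test_additive_simulation_gives_no_high_orders(self):
        space = SequenceSpace("ACGT", 4)
        f = sample_vc_landscape(space, [0, 1, 0, 0, 0], seed=11)
        data = ObservedData(space, np.arange(256), f.values)
        lam = kernel_alignment_fit(empirical_distance_correlation(data), space)
        assert lam[1] > 0
        assert np.all(lam[2:] < 0.05 * lam[1])

    def test_zero_covariances_give_zero_lambdas(self, dna2):
        tab = pd.DataFrame(
            {"d": [0, 1, 2], "covariance": [0.0, 0.0, 0.0],
             "n_pairs": [10, 10, 10], "noise_corrected": False}
        )
        np.testing.assert_allclose(kernel_alignment_fit(tab, dna2), 0.0)

    def test_single_distance_class_rejected(self, dna2):
        tab = pd.DataFrame(
            {"d": [0, 1, 2], "covariance": [1.0, np.nan, np.nan],
             "n_pairs": [10, 0, 0], "noise_corrected": False}
        )
        with pytest.raises(ValueError, match="distance classes"):
            kernel_alignment_fit(tab, dna2)


class TestPosterior:
    def test_mei_additive_completion(self):
        # observing three corners of the binary square noiselessly forces
        # the fourth to the additive completion (epsilon driven to 0)
        space = SequenceSpace("01", 2)
        data = ObservedData(space, [0, 1, 2], [0.0, 1.0, 1.0])
        post = mei(data, P=2)
        np.testing.assert_allclose(post.mean, [0.0, 1.0, 1.0, 2.0], atol=1e-9)

    def test_noiseless_interpolation_is_exact(self, trinuc3, rng):
        f = rng.normal(size=27)
        obs = rng.choice(27, size=20, replace=False)
        data = ObservedData(trinuc3, obs, f[obs])
        post = mei(data, P=2)
        np.testing.assert_allclose(post.mean[obs], f[obs], atol=1e-12)

    def test_full_observation_noiseless_returns_data(self, dna2, rng):
        y = rng.normal(size=16)
        data = ObservedData(dna2, np.arange(16), y)
        post = fit_posterior(data, VCPrior(np.array([0, 1.0, 0.5])))
        np.testing.assert_allclose(post.mean, y, atol=1e-7)
        assert post.contrast_variance({3: 1.0}) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_vc_posterior_matches_dense_closed_form(self, trinuc3, seed):
        rng = np.random.default_rng(seed)
        lam = np.array([0.0, 1.0, 0.3, 0.05])
        f = sample_vc_landscape(trinuc3, lam, seed=seed)
        train, _ = make_observations(f, 0.7, 0.05, seed=seed + 50)
        post = fit_posterior(train, VCPrior(lam))
        k = VCKernelOperator(trinuc3, lam).to_dense()
        obs = train.genotypes
        ybar = np.mean(train.y)
        kxx = k[np.ix_(obs, obs)] + np.diag(train.noise_var)
        alpha = np.linalg.solve(kxx, train.y - ybar)
        np.testing.assert_allclose(post.mean, k[:, obs] @ alpha + ybar,
                                   atol=1e-8)
        sigma = k - k[:, obs] @ np.linalg.solve(kxx, k[obs, :])
        w = rng.normal(size=27)
        assert post.contrast_variance(w) == pytest.approx(
            float(w @ sigma @ w), abs=1e-8
        )

    def test_delta_posterior_matches_dense_closed_form(self, trinuc3, rng):
        lam = np.array([0.0, 1.0, 0.3, 0.05])
        f = sample_vc_landscape(trinuc3, lam, seed=2)
        train, _ = make_observations(f, 0.7, 0.05, seed=3)
        prior = DeltaPrior(P=2, a=None)
        post = fit_posterior(train, prior)
        h = prior.scale(trinuc3) * DeltaPOperator(trinuc3, 2).to_dense()
        inv_var = np.zeros(27)
        inv_var[train.genotypes] = 1.0 / train.noise_var
        h += np.diag(inv_var)
        rhs = np.zeros(27)
        rhs[train.genotypes] = train.y / train.noise_var
        np.testing.assert_allclose(post.mean, np.linalg.solve(h, rhs),
                                   atol=1e-8)
        w = rng.normal(size=27)
        assert post.contrast_variance(w) == pytest.approx(
            float(w @ np.linalg.solve(h, w)), rel=1e-6
        )

    def test_shift_invariance(self, trinuc3, rng):
        lam = np.array([0.0, 1.0, 0.3, 0.05])
        f = sample_vc_landscape(trinuc3, lam, seed=4)
        train, _ = make_observations(f, 0.6, 0.02, seed=5)
        shifted = ObservedData(trinuc3, train.genotypes, train.y + 7.0,
                               train.noise_var)
        p1 = fit_posterior(train, VCPrior(lam))
        p2 = fit_posterior(shifted, VCPrior(lam))
        np.testing.assert_allclose(p2.mean, p1.mean + 7.0, atol=1e-6)
        w = rng.normal(size=27)
        assert p1.contrast_variance(w) == pytest.approx(
            p2.contrast_variance(w), rel=1e-5, abs=1e-9
        )

    def test_underdetermined_null_space_rejected(self, dna2):
        # Delta(2) on ACGT,l=2 leaves a 7-dimensional additive null space
        data = ObservedData(dna2, [0, 1, 2], [0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="null space"):
            mei(data, P=2)

    def test_contrast_wrappers(self, dna2, rng):
        lam = np.array([0.0, 1.0, 0.2])
        f = sample_vc_landscape(dna2, lam, seed=6)
        data = ObservedData(dna2, np.arange(16), f.values,
                            np.full(16, 0.01))
        post = fit_posterior(data, VCPrior(lam))
        m, (lo, hi) = post.mutational_effect_posterior("AA", 1, "A", "C")
        direct = post.mean[dna2.seq_to_index("AC")] - post.mean[0]
        assert m == pytest.approx(direct, abs=1e-9)
        assert lo < m < hi
        m2, _ = post.epistatic_coefficient_posterior(
            "AA", (0, "A", "C"), (1, "A", "G")
        )
        expect = (post.mean[dna2.seq_to_index("CG")]
                  - post.mean[dna2.seq_to_index("AG")]
                  - post.mean[dna2.seq_to_index("CA")]
                  + post.mean[dna2.seq_to_index("AA")])
        assert m2 == pytest.approx(expect, abs=1e-9)


class TestEvaluation:
    def test_perfect_predictions(self, dna2):
        f = np.arange(16.0)
        data = ObservedData(dna2, np.arange(16), f)
        post = fit_posterior(data, VCPrior(np.array([0, 1.0, 0.5])))
        test = ObservedData(dna2, [3, 7], f[[3, 7]])
        with pytest.warns(UserWarning, match="overlap"):
            m = evaluate_predictions(post, test, compute_variances=False)
        assert m["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_predictor_nonpositive_r2(self, dna2):
        data = ObservedData(dna2, [0], [5.0], [1e-6])
        post = fit_posterior(data, VCPrior(np.array([0, 1e-12, 0])))
        test = ObservedData(dna2, [1, 2, 3], [0.0, 1.0, 9.0])
        m = evaluate_predictions(post, test, compute_variances=False)
        assert m["r2"] <= 0.0

    def test_coverage_calibration_on_simulated_landscape(self):
        # landscape drawn from a known prior, refitted with the true
        # lambdas: 95% intervals should cover ~95% of held-out points
        space = SequenceSpace("ACGT", 4)
        lam = lambdas_from_variance_fractions(
            space, [0, 0.7, 0.2, 0.07, 0.03], total_variance=1.0
        )
        f = sample_vc_landscape(space, lam, seed=21)
        rng = np.random.default_rng(22)
        perm = rng.permutation(256)
        tr, te = perm[:128], perm[128:]
        noise = 0.058
        train = ObservedData(space, tr,
                             f.values[tr] + np.sqrt(noise)
                             * rng.standard_normal(128),
                             np.full(128, noise))
        test = ObservedData(space, te,
                            f.values[te] + np.sqrt(noise)
                            * rng.standard_normal(128),
                            np.full(128, noise))
        post = fit_posterior(train, VCPrior(lam))
        m = evaluate_predictions(post, test)
        assert m["coverage"][0.95] > 0.88
        assert m["r2"] > 0.3
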