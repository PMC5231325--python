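"""Univariate Gibbs sampler: conjugacy oracles and chain invariants."""

import numpy as np
import pytest
from scipy import stats

from overmix.mixture_mcmc import (
    MCMCConfig,
    PriorSpecUnivariate,
    allocation_full_conditional,
    run_gibbs_univariate,
    sample_means,
    sample_proportions,
    sample_variances,
    update_hyperparameters,
)

VAGUE = PriorSpecUnivariate(alpha=0.1)
HIER = PriorSpecUnivariate(alpha=0.1, mean_prior="normal_gamma", var_prior="hierarchical")


class TestAllocation:
    def test_symmetric_components_give_equal_probs(self):
        p = allocation_full_conditional(0.7, [0.5, 0.5], [1.0, 1.0], [0.3, 0.3])
        assert np.allclose(p, [0.5, 0.5])

    def test_degenerate_weight(self):
        p = allocation_full_conditional(0.7, [1.0, 0.0], [1.0, 5.0], [0.3, 0.3])
        assert np.allclose(p, [1.0, 0.0])

    def test_against_direct_density_evaluation(self):
        # independent oracle: scipy normal pdfs combined by hand
        y, lam = 1.0, np.array([0.5, 0.5])
        mu, var = np.array([1.0, 3.0]), np.array([1.0, 1.0])
        num = lam * stats.norm.pdf(y, mu, np.sqrt(var))
        expected = num / num.sum()
        assert np.allclose(
            allocation_full_conditional(y, lam, mu, var), expected, atol=1e-12
        )

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            allocation_full_conditional(0.0, [0.0, 0.0], [0, 1], [1, 1])


class TestProportions:
    def test_posterior_mean_matches_dirichlet_moment(self, rng):
        # E[lambda_1] = (alpha + N_1) / (K alpha + N) = 3.5 / 5
        draws = np.array(
            [sample_proportions([3, 1], 0.5, rng) for _ in range(100_000)]
        )
        se = draws[:, 0].std() / np.sqrt(len(draws))
        assert abs(draws[:, 0].mean() - 0.7) < 3 * se

    def test_zero_counts_recover_prior(self, rng):
        draws = np.array(
            [sample_proportions([0, 0, 0], 2.0, rng) for _ in range(50_000)]
        )
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - 1 / 3) < 3 * se)

    def test_draws_are_simplex_points(self, rng):
        for counts in ([5, 5], [0, 10, 3], [1000, 0]):
            lam = sample_proportions(counts, 0.01, rng)
            assert np.all(lam >= 0) and abs(lam.sum() - 1.0) < 1e-10

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            sample_proportions([1, 2], 0.0, rng)
        with pytest.raises(ValueError):
            sample_proportions([-1, 2], 0.5, rng)


class TestMeans:
    def test_single_class_posterior_matches_conjugate_closed_form(self, rng):
        # mu_post = (sum y / s2) / (n / s2 + 1 / var0), var_post = 1/(n/s2 + 1/var0)
        y = rng.normal(2.0, 0.5, size=2000)
        z = np.zeros(len(y), dtype=int)
        s2 = 0.25
        prec = len(y) / s2 + 1 / VAGUE.var0
        mu_post = (y.sum() / s2) / prec
        draws = np.array(
            [sample_means(y, z, np.array([s2]), VAGUE, None, rng)[0] for _ in range(5000)]
        )
        assert abs(draws.mean() - mu_post) < 4 * np.sqrt(1 / prec) / np.sqrt(5000) + 1e-3
        assert abs(draws.std() - np.sqrt(1 / prec)) < 0.1 * np.sqrt(1 / prec)

    def test_empty_class_reverts_to_prior(self, rng):
        y = np.array([1.0, 2.0])
        z = np.zeros(2, dtype=int)  # class 1 empty
        draws = np.array(
            [
                sample_means(y, z, np.array([0.1, 0.1]), VAGUE, None, rng)[1]
                for _ in range(20_000)
            ]
        )
        assert abs(draws.mean()) < 3 * np.sqrt(1000 / 20_000)
        assert abs(draws.std() - np.sqrt(1000)) < 1.0


class TestVariances:
    def test_uniform_prior_support(self, rng):
        y = rng.normal(0, 3.0, size=400)
        z = rng.integers(0, 3, size=400)
        for _ in range(50):
            v = sample_variances(y, z, np.zeros(3), VAGUE, None, rng)
            assert np.all((v > 0) & (v < 10))

    def test_hierarchical_empty_class_prior_reversion(self, rng):
        # precision of an empty class ~ Gamma(1.25, 1/(2 C0))
        y = np.array([0.5])
        z = np.array([0], dtype=int)
        C0 = 2.0
        taus = []
        for _ in range(50_000):
            v = sample_variances(y, z, np.zeros(2), HIER, (0.0, 1.0, C0), rng)
            taus.append(1.0 / v[1])
        taus = np.asarray(taus)
        shape, rate = 1.25, 1.0 / (2 * C0)
        assert abs(taus.mean() - shape / rate) < 4 * taus.std() / np.sqrt(len(taus))

    def test_single_class_consistency(self, rng):
        # truth sigma^2 = 0.0625 (SD 0.25); posterior concentrates there
        y = rng.normal(1.0, 0.25, size=10_000)
        z = np.zeros(len(y), dtype=int)
        mu = np.array([y.mean()])
        draws = np.array(
            [sample_variances(y, z, mu, VAGUE, None, rng)[0] for _ in range(2000)]
        )
        assert abs(draws.mean() - 0.0625) < 3 * draws.std()


class TestHyperparameters:
    def test_zero_deviation_eta_rate_is_prior_rate(self, rng):
        # all mu_k == b0 => eta | ... ~ Gamma(nu1 + K/2, nu2)
        K = 6
        b0 = 1.3
        draws = []
        for _ in range(50_000):
            _, eta, _ = update_hyperparameters(
                np.full(K, b0),
                np.full(K, 0.1),
                PriorSpecUnivariate(alpha=0.1, mean_prior="normal_gamma"),
                (b0, 2.0),
                rng,
                hyper_state=(b0, 1.0, 1.0),
            )
            draws.append(eta)
        draws = np.asarray(draws)
        shape, rate = 0.5 + K / 2, 0.5
        assert abs(draws.mean() - shape / rate) < 4 * draws.std() / np.sqrt(len(draws))

    def test_b0_matches_conjugate_normal_oracle(self, rng):
        # pin eta via a sharply concentrated hyperprior so the b0 full
        # conditional is exactly the closed-form normal combination
        means = np.array([0.8, 1.1, 1.4])
        eta, R, m0 = 0.5, 2.0, 1.0
        prior = PriorSpecUnivariate(
            alpha=0.1, mean_prior="normal_gamma", nu1=1e6, nu2=1e6 / eta
        )
        like_var = eta * R**2
        M0 = 1.0 / prior.M0_inv
        prec = 1 / M0 + len(means) / like_var
        mean_exact = (m0 / M0 + means.sum() / like_var) / prec
        draws = np.array(
            [
                update_hyperparameters(
                    means, np.full(3, 0.1), prior, (m0, R), rng, (0.0, eta, 1.0)
                )[0]
                for _ in range(50_000)
            ]
        )
        assert abs(draws.mean() - mean_exact) < 4 * draws.std() / np.sqrt(len(draws))
        assert abs(draws.std() - np.sqrt(1 / prec)) < 0.05 * np.sqrt(1 / prec)

    def test_constant_data_errors(self, rng):
        with pytest.raises(ValueError):
            update_hyperparameters(np.ones(2), np.ones(2), HIER, (1.0, 0.0), rng)


class TestGibbsChain:
    def test_empty_run_returns_empty_container(self, a1_data):
        cfg = MCMCConfig(K_max=4, n_iter=0, burn_in=5, seed=1)
        draws = run_gibbs_univariate(a1_data, VAGUE, cfg)
        assert draws.M == 0

    def test_occupancy_conservation_and_simplex(self, a2_data):
        cfg = MCMCConfig(K_max=10, n_iter=300, burn_in=50, seed=4)
        draws = run_gibbs_univariate(a2_data, VAGUE, cfg)
        assert np.all(draws.counts.sum(axis=1) == 500)
        assert np.allclose(draws.lambda_.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(draws.variances > 0)
        assert np.all(draws.variances < 10)  # uniform prior support

    def test_seed_determinism(self, a1_data):
        cfg = MCMCConfig(K_max=5, n_iter=100, burn_in=20, seed=9)
        d1 = run_gibbs_univariate(a1_data, VAGUE, cfg)
        d2 = run_gibbs_univariate(a1_data, VAGUE, cfg)
        assert np.array_equal(d1.means, d2.means)
        assert np.array_equal(d1.counts, d2.counts)

    def test_kmax1_posterior_matches_conjugate_oracle(self, rng):
        """K_max=1: MCMC mean of mu agrees with the normal conjugate posterior."""
        y = rng.normal(1.0, 0.25, size=500)
        cfg = MCMCConfig(K_max=1, n_iter=2000, burn_in=300, seed=2)
        draws = run_gibbs_univariate(y, PriorSpecUnivariate(alpha=0.5), cfg)
        s2 = draws.variances.mean()
        prec = len(y) / s2 + 1 / 1000.0
        mu_exact = (y.sum() / s2) / prec
        mc = draws.means[:, 0]
        assert abs(mc.mean() - mu_exact) < 4 * mc.std() / np.sqrt(200)  # ESS-ish
        assert abs(mc.std() - np.sqrt(1 / prec)) < 0.25 * np.sqrt(1 / prec)

    def test_alpha_warning_at_or_above_d_over_2(self, a1_data):
        cfg = MCMCConfig(K_max=3, n_iter=10, burn_in=0, seed=1)
        with pytest.warns(UserWarning, match="d/2"):
            run_gibbs_univariate(a1_data, PriorSpecUnivariate(alpha=2.0), cfg)

    def test_sparser_alpha_empties_more_classes(self, a1_data):
        """Directional check of the overfitted-mixture asymptotics: on
        homogeneous data, alpha=2 (above d/2) keeps more classes occupied
        than alpha=0.01."""
        import warnings

        res = {}
        for alpha in (0.01, 2.0):
            cfg = MCMCConfig(K_max=10, n_iter=800, burn_in=300, seed=6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                draws = run_gibbs_univariate(
                    a1_data, PriorSpecUnivariate(alpha=alpha), cfg
                )
            res[alpha] = (draws.counts > 0).sum(axis=1).mean()
        assert res[2.0] > res[0.01]

    def test_hierarchical_priors_run_and_record_hypers(self, a1_data):
        cfg = MCMCConfig(K_max=6, n_iter=200, burn_in=50, seed=3)
        draws = run_gibbs_univariate(a1_data, HIER, cfg)
        assert draws.hyper_draws is not None and draws.hyper_draws.shape == (200, 3)
        assert np.all(draws.hyper_draws[:, 1] > 0)  # eta
        assert np.all(draws.hyper_draws[:, 2] > 0)  # C0
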