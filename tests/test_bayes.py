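"""NIW conjugacy, divergences and the SV score."""

import math

import numpy as np
import pytest
from scipy.stats import invwishart, multivariate_normal

from topovar import (GaussianParams, InsufficientDataError, NIWPrior, SVResult,
                     detect, fit_posterior, jeffreys, kl_normal,
                     sample_posterior, sv_score)

from oracles import kl_by_quadrature, random_spd_2x2


class TestFitPosterior:
    def test_update_equations_at_n5(self, rng):
        obs = rng.normal(size=(5, 2))
        post = fit_posterior(obs)
        assert post.nu == pytest.approx(7.0)     # nu0=2 + N=5
        assert post.kappa == pytest.approx(5.0)  # kappa0=+0 limit
        np.testing.assert_allclose(post.m, obs.mean(axis=0))
        np.testing.assert_allclose(post.psi, np.eye(2) + post.scatter)

    def test_identical_observations_give_zero_scatter(self):
        x = np.array([1.3, 0.7])
        post = fit_posterior(np.tile(x, (5, 1)))
        np.testing.assert_allclose(post.scatter, 0.0, atol=1e-12)
        np.testing.assert_allclose(post.psi, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(post.m, x)

    def test_scatter_matches_hand_computation(self):
        obs = [(1.0, 2.0), (1.5, 2.5), (0.5, 1.5), (2.0, 3.5),
               (1.0, 1.0), (0.0, 1.5)]
        # scatter about the mean, accumulated with explicit loops
        mean = [sum(x[i] for x in obs) / len(obs) for i in range(2)]
        expected = [[0.0, 0.0], [0.0, 0.0]]
        for x in obs:
            d = [x[0] - mean[0], x[1] - mean[1]]
            for i in range(2):
                for j in range(2):
                    expected[i][j] += d[i] * d[j]
        post = fit_posterior(np.array(obs))
        np.testing.assert_allclose(post.psi, np.eye(2) + np.array(expected),
                                   rtol=1e-12)

    def test_too_few_or_invalid_observations_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_posterior(rng.normal(size=(4, 2)))
        bad = rng.normal(size=(6, 2))
        bad[2, 1] = np.nan
        with pytest.raises(ValueError):
            fit_posterior(bad)

    def test_conjugacy_against_grid_evaluated_bayes_rule(self, rng):
        """log(prior x likelihood) - log(analytic posterior density) must
        be the same constant at every (mu, Sigma) grid point."""
        obs = rng.normal([1.0, 0.5], [1.0, 0.6], size=(5, 2))
        prior = NIWPrior()
        post = fit_posterior(obs, prior)

        def log_unnormalised(mu, sigma):
            # kappa0=+0 prior: N(m0, Sigma/kappa0) tends to an improper
            # density proportional to |Sigma|^(-1/2) in mu, times
            # InvWishart(Psi0, nu0) in Sigma
            lp = (invwishart.logpdf(sigma, df=prior.nu0, scale=prior.psi0)
                  - 0.5 * np.linalg.slogdet(sigma)[1])
            ll = multivariate_normal(mu, sigma).logpdf(obs).sum()
            return lp + ll

        def log_posterior(mu, sigma):
            return (invwishart.logpdf(sigma, df=post.nu, scale=post.psi)
                    + multivariate_normal(post.m, sigma / post.kappa).logpdf(mu))

        diffs = []
        for _ in range(12):
            mu = post.m + rng.normal(0.0, 0.5, size=2)
            sigma = random_spd_2x2(rng)
            diffs.append(log_unnormalised(mu, sigma) - log_posterior(mu, sigma))
        diffs = np.array(diffs)
        assert np.ptp(diffs) <= 1e-6 * max(1.0, abs(diffs.mean()))

    def test_positive_kappa0_reduces_to_weighted_mean(self, rng):
        obs = rng.normal(size=(8, 2))
        prior = NIWPrior(m0=np.array([5.0, -5.0]), kappa0=2.0)
        post = fit_posterior(obs, prior)
        assert post.kappa == pytest.approx(10.0)
        np.testing.assert_allclose(
            post.m, (2.0 * prior.m0 + 8.0 * obs.mean(axis=0)) / 10.0)


class TestSamplePosterior:
    def test_deterministic_under_seed(self, rng):
        post = fit_posterior(rng.normal(size=(10, 2)))
        a = sample_posterior(post, 5, seed=42)
        b = sample_posterior(post, 5, seed=42)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.mu, db.mu)
            np.testing.assert_array_equal(da.sigma, db.sigma)

    def test_moments_match_inverse_wishart_and_mean(self):
        psi = np.array([[2.0, 0.5], [0.5, 1.0]])
        from topovar.bayes import NIWPosterior
        post = NIWPosterior(psi=psi, nu=12.0, m=np.array([1.0, -1.0]),
                            kappa=9.0, n_obs=9,
                            sample_mean=np.array([1.0, -1.0]),
                            scatter=psi - np.eye(2))
        draws = sample_posterior(post, 50_000, seed=3)
        sigmas = np.array([d.sigma for d in draws])
        mus = np.array([d.mu for d in draws])
        # E[Sigma] = Psi / (nu - d - 1) with d = 2
        np.testing.assert_allclose(sigmas.mean(axis=0), psi / 9.0, rtol=0.02)
        np.testing.assert_allclose(mus.mean(axis=0), post.m, atol=0.01)


class TestDivergences:
    def test_zero_iff_identical(self):
        p = GaussianParams([0.3, -0.2], [[1.5, 0.3], [0.3, 0.8]])
        assert kl_normal(p, p) == pytest.approx(0.0, abs=1e-12)
        assert jeffreys(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_shift_gives_half_nat(self):
        p = GaussianParams([0.0, 0.0], np.eye(2))
        q = GaussianParams([1.0, 0.0], np.eye(2))
        assert kl_normal(p, q) == pytest.approx(0.5, abs=1e-12)
        assert kl_normal(p, q) == pytest.approx(
            kl_by_quadrature(p.mu, p.sigma, q.mu, q.sigma), abs=1e-10)

    def test_doubled_covariance_closed_form(self):
        p = GaussianParams([0.4, 0.4], np.eye(2))
        q = GaussianParams([0.4, 0.4], 2.0 * np.eye(2))
        assert kl_normal(p, q) == pytest.approx(math.log(2.0) - 0.5, abs=1e-12)

    def test_two_sd_separation_gives_jeffreys_four(self):
        p = GaussianParams([0.0, 0.0], np.eye(2))
        q = GaussianParams([2.0, 0.0], np.eye(2))
        assert jeffreys(p, q) == pytest.approx(4.0, abs=1e-12)

    def test_closed_form_matches_quadrature_on_random_pairs(self, rng):
        for _ in range(20):
            p = GaussianParams(rng.normal(size=2), random_spd_2x2(rng))
            q = GaussianParams(rng.normal(size=2), random_spd_2x2(rng))
            oracle = (kl_by_quadrature(p.mu, p.sigma, q.mu, q.sigma)
                      + kl_by_quadrature(q.mu, q.sigma, p.mu, p.sigma))
            assert jeffreys(p, q) == pytest.approx(oracle, abs=1e-4)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(1000):
            p = GaussianParams(rng.normal(size=2), random_spd_2x2(rng))
            q = GaussianParams(rng.normal(size=2), random_spd_2x2(rng))
            d = jeffreys(p, q)
            assert d >= -1e-12
            assert d == pytest.approx(jeffreys(q, p), rel=1e-12)

    def test_singular_covariance_rejected(self):
        with pytest.raises(Exception):
            GaussianParams([0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])


class TestSVScore:
    def test_score_is_linear_interpolation_percentile_of_draws(self, rng):
        post1 = fit_posterior(rng.normal(size=(30, 2)))
        post2 = fit_posterior(rng.normal(size=(30, 2)))
        res = sv_score(post1, post2, n_draws=200, seed=5)
        assert res.sv_score == pytest.approx(
            float(np.percentile(res.divergence_samples, 5.0)))
        assert (res.divergence_samples >= -1e-12).all()

    def test_self_comparison_not_detected(self, rng):
        obs = rng.normal([2.0, 1.0], [0.3, 0.2], size=(50, 2))
        post = fit_posterior(obs)
        res = sv_score(post, post, n_draws=1000, seed=0)
        assert res.sv_score < 4.0
        assert not res.detected

    def test_mahalanobis_limit_at_large_n(self, rng):
        """With shared covariance and abundant data the SV score converges
        on the squared Mahalanobis distance between the means."""
        sigma = np.array([[1.0, 0.3], [0.3, 0.7]])
        mu1, mu2 = np.array([0.0, 0.0]), np.array([1.2, -0.6])
        chol = np.linalg.cholesky(sigma)
        x1 = mu1 + rng.standard_normal((10_000, 2)) @ chol.T
        x2 = mu2 + rng.standard_normal((10_000, 2)) @ chol.T
        res = sv_score(fit_posterior(x1), fit_posterior(x2),
                       n_draws=1000, seed=1)
        diff = mu2 - mu1
        expected = float(diff @ np.linalg.solve(sigma, diff))
        assert res.sv_score == pytest.approx(expected, rel=0.10)

    def test_monotone_in_mean_separation(self):
        """Median SV score over replicates grows with the planted mean
        separation, covariances and sample size held fixed."""
        separations = [0.0, 1.0, 2.0, 4.0]
        medians = []
        for sep in separations:
            scores = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                x1 = rng.normal([0.0, 0.0], 1.0, size=(40, 2))
                x2 = rng.normal([sep, 0.0], 1.0, size=(40, 2))
                scores.append(sv_score(fit_posterior(x1), fit_posterior(x2),
                                       n_draws=300, seed=rep).sv_score)
            medians.append(float(np.median(scores)))
        assert all(b > a for a, b in zip(medians, medians[1:]))

    def test_swap_of_control_and_case_within_mc_error(self, rng):
        x1 = rng.normal([0.0, 0.0], 1.0, size=(60, 2))
        x2 = rng.normal([1.5, 0.0], 1.0, size=(60, 2))
        p1, p2 = fit_posterior(x1), fit_posterior(x2)
        forward = sv_score(p1, p2, n_draws=4000, seed=7).sv_score
        backward = sv_score(p2, p1, n_draws=4000, seed=8).sv_score
        assert backward == pytest.approx(forward, rel=0.15)


class TestDetect:
    @pytest.mark.parametrize("score,expected",
                             [(4.0, False), (4.01, True), (0.0, False)])
    def test_threshold_is_strict(self, score, expected):
        res = SVResult(identity=None, divergence_samples=np.array([score]),
                       sv_score=score, threshold=4.0,
                       detected=score > 4.0)
        assert detect(res, threshold=4.0) is expected
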