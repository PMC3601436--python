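"""Prior machinery and the data-augmentation Gibbs sampler."""

import numpy as np
import pytest
from scipy import integrate, stats

from ivtreat import (
    ErrorSpec,
    PriorSpec,
    StructuralParams,
    eta_transform_check,
    fit_bayes,
    fit_mle,
    fit_ols,
    nu_for_variance,
    prior_moments,
    prior_sensitivity_sweep,
    rho_prior_logpdf,
    simulate_dataset,
)


class TestRhoPrior:
    def test_uniform_case_is_constant_half(self):
        prior = PriorSpec(nu1=1, nu2=1)
        for r in (-0.9, -0.3, 0.0, 0.5, 0.99):
            assert rho_prior_logpdf(r, prior) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("nu", [0.5, 1.0, 2.0, 10.0])
    def test_integrates_to_one(self, nu):
        prior = PriorSpec(nu1=nu, nu2=nu)
        val, _ = integrate.quad(
            lambda r: np.exp(rho_prior_logpdf(r, prior)), -1, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("nu", [0.3, 1.0, 4.0])
    def test_symmetric_shapes_give_symmetric_density(self, nu):
        prior = PriorSpec(nu1=nu, nu2=nu)
        for r in (0.1, 0.45, 0.8):
            assert rho_prior_logpdf(r, prior) == pytest.approx(
                rho_prior_logpdf(-r, prior), abs=1e-12
            )

    def test_outside_support_is_neg_inf_not_exception(self):
        prior = PriorSpec()
        assert rho_prior_logpdf(1.0, prior) == -np.inf
        assert rho_prior_logpdf(-1.5, prior) == -np.inf


class TestPriorMoments:
    def test_uniform_variance_one_third(self):
        mean, var = prior_moments(PriorSpec(nu1=1, nu2=1))
        assert mean == 0.0
        assert var == pytest.approx(1 / 3)

    def test_variance_supremum_as_nu_vanishes(self):
        _, var = prior_moments(PriorSpec(nu1=1e-6, nu2=1e-6))
        assert var == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("nu", [0.5, 2.0, 7.0])
    def test_closed_form_matches_sampling_oracle(self, nu, rng):
        """Transformed-Beta Monte Carlo draws reproduce mean 0 and variance
        1/(2*nu + 1)."""
        mean, var = prior_moments(PriorSpec(nu1=nu, nu2=nu))
        assert mean == 0.0
        assert var == pytest.approx(1 / (2 * nu + 1))
        draws = 2 * rng.beta(nu, nu, size=1_000_000) - 1
        mc_se_var = np.sqrt(np.var((draws - draws.mean()) ** 2) / draws.size)
        assert abs(draws.var() - var) < 3 * mc_se_var

    def test_variance_to_nu_roundtrip(self):
        for v in (0.9, 1 / 3, 0.01):
            nu = nu_for_variance(v)
            assert prior_moments(PriorSpec(nu1=nu, nu2=nu))[1] == pytest.approx(v)
        with pytest.raises(ValueError):
            nu_for_variance(1.5)


class TestEtaTransform:
    @pytest.mark.parametrize("sigma_y", [0.5, 1.0, 2.0])
    def test_uniform_rho_induces_t2_density(self, sigma_y):
        """Change of variables through eta = rho/(sigma*sqrt(1-rho^2)) maps
        the uniform prior to the printed t(2)-form density pointwise."""
        chk = eta_transform_check(PriorSpec(nu1=1, nu2=1), sigma_y)
        assert chk.max_abs_diff < 1e-8
        assert chk.integral == pytest.approx(1.0, abs=1e-6)
        assert chk.passed

    def test_value_at_origin(self):
        chk = eta_transform_check(PriorSpec(nu1=1, nu2=1), 1.0)
        i0 = np.argmin(np.abs(chk.eta_grid))
        assert chk.printed[i0] == pytest.approx(0.5)

    def test_requires_uniform_prior(self):
        with pytest.raises(ValueError, match="uniform"):
            eta_transform_check(PriorSpec(nu1=2, nu2=2), 1.0)


class TestGibbsSampler:
    def test_conjugate_subcase_matches_closed_form(self):
        """With rho fixed at 0 and sigma_y known, the outcome-coefficient
        posterior is exactly normal with known mean/covariance; the sampler
        must reproduce it within Monte-Carlo error."""
        p = StructuralParams.collapsed(rho=0.0, sigma_y=1.0)
        d = simulate_dataset(p, ErrorSpec("normal", 0.0, 1.0), 500, seed=21)
        post = fit_bayes(
            d, iters=4000, warmup=500, chains=1, seed=3, fix_rho=0.0, fix_sigma=1.0
        )
        W = np.column_stack([d.z, d.X])
        prec = W.T @ W / 1.0 + np.eye(3) / 100.0**2
        mean = np.linalg.solve(prec, W.T @ d.y)
        sd = np.sqrt(np.diag(np.linalg.inv(prec)))
        names = ["beta1", "beta2_0", "beta2_1"]
        got_mean = post.mean()[names].to_numpy()
        got_sd = post.sd()[names].to_numpy()
        ess = post.diagnostics.loc[names, "ess"].to_numpy()
        np.testing.assert_array_less(np.abs(got_mean - mean), 4 * sd / np.sqrt(ess))
        np.testing.assert_allclose(got_sd, sd, rtol=0.15)

    def test_posterior_agrees_with_mle_under_uniform_prior(self):
        """Diffuse priors: posterior means of (beta1, rho) sit within 3
        posterior SDs of the MLE on the same data."""
        p = StructuralParams.collapsed(rho=0.721, sigma_y=1.5)
        d = simulate_dataset(p, ErrorSpec("normal", 0.721, 1.5), 2000, seed=23)
        post = fit_bayes(d, iters=4000, warmup=1500, chains=2, seed=9)
        mle = fit_mle(d)
        for name in ("beta1", "rho", "sigma_y"):
            assert abs(post.mean()[name] - mle.estimates[name]) < 3 * post.sd()[name]

    def test_point_mass_prior_recovers_ols(self):
        """A near point-mass prior on rho at 0 forces the posterior mean of
        beta1 to the OLS estimate even under strong true selection."""
        p = StructuralParams.collapsed(rho=0.721, sigma_y=1.5)
        d = simulate_dataset(p, ErrorSpec("normal", 0.721, 1.5), 2000, seed=29)
        prior = PriorSpec.for_rho_variance(1e-4 / 3)
        post = fit_bayes(d, prior, iters=2500, warmup=1000, chains=1, seed=11)
        ols = fit_ols(d).beta1
        mle = fit_mle(d).beta1
        b = post.mean()["beta1"]
        assert abs(b - ols) < 0.2 * abs(ols - mle)
        assert abs(post.mean()["rho"]) < 0.05

    def test_reproducible_given_seed(self):
        p = StructuralParams.collapsed(rho=0.3, sigma_y=1.0)
        d = simulate_dataset(p, ErrorSpec("normal", 0.3, 1.0), 300, seed=5)
        a = fit_bayes(d, iters=200, warmup=100, chains=1, seed=42)
        b = fit_bayes(d, iters=200, warmup=100, chains=1, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_contracts_with_sample_size(self):
        """Doubling n shrinks the posterior SD of beta1 by about sqrt(2)."""
        p = StructuralParams.collapsed(rho=0.5, sigma_y=1.0)
        sds = []
        # n large enough for the posterior to be near its asymptotic shape
        for n in (3000, 6000):
            d = simulate_dataset(p, ErrorSpec("normal", 0.5, 1.0), n, seed=31)
            post = fit_bayes(d, iters=5000, warmup=1500, chains=2, seed=13)
            sds.append(post.sd()["beta1"])
        ratio = sds[0] / sds[1]
        assert np.sqrt(2) * 0.8 < ratio < np.sqrt(2) * 1.2

    def test_prior_draw_constraints_hold(self):
        """Posterior draws respect the parameter space: |rho| < 1,
        sigma_y > 0."""
        p = StructuralParams.collapsed(rho=0.3, sigma_y=1.0)
        d = simulate_dataset(p, ErrorSpec("normal", 0.3, 1.0), 300, seed=6)
        post = fit_bayes(d, iters=300, warmup=100, chains=1, seed=1)
        flat = post.to_frame()
        assert (flat["rho"].abs() < 1).all()
        assert (flat["sigma_y"] > 0).all()


class TestPriorSensitivitySweep:
    def test_single_cell_equals_direct_fit(self):
        p = StructuralParams.collapsed(rho=0.3, sigma_y=1.0)
        d = simulate_dataset(p, ErrorSpec("normal", 0.3, 1.0), 300, seed=8)
        tab = prior_sensitivity_sweep(d, [1 / 3], iters=300, warmup=150, chains=1, seed=17)
        direct = fit_bayes(
            d, PriorSpec.for_rho_variance(1 / 3), iters=300, warmup=150, chains=1, seed=17
        )
        assert tab.loc[0, "beta1_mean"] == pytest.approx(direct.mean()["beta1"])
        assert tab.loc[0, "nu"] == pytest.approx(1.0)

    def test_beta1_moves_from_ols_to_mle_and_ate_is_stable(self):
        """Across the prior-variance grid the posterior mean of beta1
        travels from OLS-like (tight prior at rho=0) toward MLE-like
        (diffuse), while the ATE summary moves far less."""
        p = StructuralParams.collapsed(rho=0.721, sigma_y=1.5)
        d = simulate_dataset(p, ErrorSpec("normal", 0.721, 1.5), 2000, seed=37)
        tab = prior_sensitivity_sweep(
            d, [1e-4 / 3, 0.9], iters=2500, warmup=1000, chains=1, seed=19
        )
        ols = fit_ols(d).beta1
        mle = fit_mle(d).beta1
        tight, diffuse = tab.loc[0], tab.loc[1]
        assert abs(tight["beta1_mean"] - ols) < abs(tight["beta1_mean"] - mle)
        assert abs(diffuse["beta1_mean"] - mle) < abs(diffuse["beta1_mean"] - ols)
        beta1_range = abs(diffuse["beta1_mean"] - tight["beta1_mean"])
        ate_range = abs(diffuse["ate_mean"] - tight["ate_mean"])
        assert ate_range < beta1_range
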