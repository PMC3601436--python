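"""Observed-data likelihood against numerical-integration oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess3

from ivtreat import (
    ErrorSpec,
    IVDataset,
    StructuralParams,
    fit_mle,
    loglik,
    profile_rho,
    simulate_dataset,
)
from ivtreat import test_exclusion as exclusion_test
from ivtreat.likelihood import _negloglik_and_grad


def _random_case(seed):
    """A random (params, data) pair; evaluation params differ from the
    generating ones so the check is not anchored at the truth."""
    rng = np.random.default_rng(seed)
    gen = StructuralParams.collapsed(
        beta1=rng.normal(), rho=rng.uniform(-0.6, 0.6), sigma_y=rng.uniform(0.7, 1.8)
    )
    data = simulate_dataset(
        gen, ErrorSpec("normal", rho=gen.rho, sigma_y=gen.sigma_y), 50, seed=seed + 1000
    )
    eval_params = StructuralParams(
        beta1=rng.normal(),
        beta2=rng.normal(size=2),
        theta1=rng.normal(size=1) * 0.5,
        theta2=rng.normal(size=2) * 0.5,
        rho=rng.uniform(-0.85, 0.85),
        sigma_y=rng.uniform(0.6, 2.0),
        beta3=rng.normal(size=1) * 0.2,
    )
    return eval_params, data


def _loglik_by_quadrature(params: StructuralParams, data: IVDataset) -> float:
    """Independent oracle: integrate the joint normal density of
    (y, latent index) over the region selected by each observed z.

    Works in log space (trapezoid over the joint logpdf) so deep-tail
    observations keep full relative precision."""
    from scipy.special import logsumexp

    mu_y = params.beta1 * data.z + data.X @ params.beta2 + data.U @ params.beta3
    mu_z = data.U @ params.theta1 + data.X @ params.theta2
    rho, sig = params.rho, params.sigma_y
    cov = np.array([[sig * sig, rho * sig], [rho * sig, 1.0]])
    total = 0.0
    for i in range(data.n):
        mv = stats.multivariate_normal(mean=[mu_y[i], mu_z[i]], cov=cov)
        lo, hi = (0.0, np.inf) if data.z[i] > 0.5 else (-np.inf, 0.0)
        # window wide enough to hold all mass of the slice through y_i
        center = mu_z[i] + rho * (data.y[i] - mu_y[i]) / sig
        a = max(lo, center - 20.0) if np.isfinite(lo) else center - 20.0
        b = min(hi, center + 20.0) if np.isfinite(hi) else center + 20.0
        if b <= a:  # region excludes the mass center: hug the boundary
            a, b = (lo, lo + 30.0) if np.isfinite(lo) else (hi - 30.0, hi)
        ts = np.linspace(a, b, 8001)
        pts = np.column_stack([np.full_like(ts, data.y[i]), ts])
        logvals = mv.logpdf(pts)
        dt = ts[1] - ts[0]
        # composite Simpson in log space (all weights positive)
        w = np.full_like(ts, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        total += logsumexp(logvals + np.log(w / 3.0)) + np.log(dt)
    return total


class TestLoglik:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_latent_variable_quadrature(self, seed):
        """Closed-form likelihood equals brute-force integration over the
        latent selection index, to 1e-6 per observation."""
        params, data = _random_case(seed)
        closed = loglik(params, data)
        brute = _loglik_by_quadrature(params, data)
        assert abs(closed - brute) < 1e-6 * data.n

    def test_factorizes_at_rho_zero(self, data_exo, params_exo):
        """At rho = 0 the likelihood is exactly (normal density of y) +
        (probit likelihood of z), computed via independent routes."""
        p = params_exo
        mu_y = p.beta1 * data_exo.z + data_exo.X @ p.beta2
        part_y = stats.norm.logpdf(data_exo.y, loc=mu_y, scale=p.sigma_y).sum()
        V = np.column_stack([data_exo.U, data_exo.X])
        theta = np.concatenate([p.theta1, p.theta2])
        part_z = sm.Probit(data_exo.z, V).loglike(theta)
        assert loglik(p, data_exo) == pytest.approx(part_y + part_z, abs=1e-10 * data_exo.n)

    def test_translation_invariance(self, data_main, params_main):
        """Shifting x by c while moving the intercept by -beta2*c (and the
        selection intercept by -theta2*c) leaves the likelihood unchanged."""
        c = 1.7
        X2 = data_main.X.copy()
        X2[:, 1] += c
        d2 = IVDataset(data_main.y, data_main.z, X2, data_main.U)
        p = params_main
        p2 = p.with_(
            beta2=np.array([p.beta2[0] - p.beta2[1] * c, p.beta2[1]]),
            theta2=np.array([p.theta2[0] - p.theta2[1] * c, p.theta2[1]]),
        )
        assert loglik(p2, d2) == pytest.approx(loglik(p, data_main), rel=1e-12)

    def test_smooth_in_rho(self, data_main, params_main):
        """Continuity across rho in (-0.99, 0.99) on fixed data: every value
        sits near the midpoint of its neighbours (a genuine jump would leave
        a second-difference spike far above the local curvature)."""
        grid = np.linspace(-0.98, 0.98, 393)
        vals = np.array([loglik(params_main.with_(rho=r), data_main) for r in grid])
        assert np.isfinite(vals).all()
        d = np.diff(vals)
        second = np.abs(d[1:] - d[:-1])
        assert np.all(second <= 0.5 * (np.abs(d[1:]) + np.abs(d[:-1])) + 1.0)

    def test_boundary_rho_rejected(self, data_main, params_main):
        with pytest.raises(ValueError, match="rho"):
            loglik(params_main.with_(rho=1.0), data_main)

    def test_analytic_gradient_matches_finite_differences(self, data_main):
        rng = np.random.default_rng(5)
        # 8 free parameters: beta1, beta2 (2), theta1 (1), theta2 (2),
        # atanh(rho), log(sigma_y)
        vec = np.r_[rng.normal(size=6) * 0.5, 0.3, 0.1]
        f = lambda v: _negloglik_and_grad(v, data_main, False)[0]
        _, grad = _negloglik_and_grad(vec, data_main, False)
        num = np.array(
            [(f(vec + 1e-6 * e) - f(vec - 1e-6 * e)) / 2e-6 for e in np.eye(8)]
        )
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-3)


class TestFitMLE:
    def test_recovers_truth_on_exogenous_data(self, params_exo):
        """rho = 0 data: across datasets the mean standardized rho-hat is
        near 0 and beta1-hat tracks the OLS estimate (single datasets can
        legitimately wander along the weak-instrument (beta1, rho) ridge)."""
        from ivtreat import fit_ols

        e = ErrorSpec("normal", rho=0.0, sigma_y=params_exo.sigma_y)
        zs, gaps = [], []
        for s in range(10):
            d = simulate_dataset(params_exo, e, 2000, seed=400 + s)
            fit = fit_mle(d)
            assert fit.converged
            zs.append(fit.estimates["rho"] / fit.se["rho"])
            ols = fit_ols(d)
            gaps.append((fit.beta1 - ols.beta1) / ols.se["beta1"])
        assert abs(np.mean(zs)) < 3 / np.sqrt(10)
        assert abs(np.mean(gaps)) < 3 / np.sqrt(10)

    def test_corrects_selection_bias(self, data_main):
        """With rho = 0.721 the MLE pulls beta1 back toward the truth that
        OLS badly overestimates."""
        fit = fit_mle(data_main)
        assert fit.converged
        assert abs(fit.beta1 - (-0.793)) < 4 * fit.se["beta1"]
        assert abs(fit.estimates["rho"] - 0.721) < 4 * fit.se["rho"]

    def test_se_matches_independent_hessian(self, data_main):
        """Delta-method SEs equal the inverse of an independently computed
        finite-difference Hessian (function values only) within 1%."""
        fit = fit_mle(data_main)
        est = fit.estimates
        xopt = np.r_[
            est.iloc[:-2].to_numpy(), np.arctanh(est["rho"]), np.log(est["sigma_y"])
        ]
        H = approx_hess3(xopt, lambda v: _negloglik_and_grad(v, data_main, False)[0])
        vcov_t = np.linalg.inv(0.5 * (H + H.T))
        jac = np.ones(len(xopt))
        jac[-2] = 1 - est["rho"] ** 2
        jac[-1] = est["sigma_y"]
        se = np.sqrt(np.diag(vcov_t * np.outer(jac, jac)))
        np.testing.assert_allclose(fit.se.to_numpy(), se, rtol=0.01)


class TestProfileRho:
    def test_profile_peaks_at_unconstrained_mle(self, data_main):
        fit = fit_mle(data_main)
        rho_hat = float(fit.estimates["rho"])
        grid = np.array([rho_hat - 0.1, rho_hat, rho_hat + 0.1])
        curve = profile_rho(data_main, grid)
        assert curve.argmax == pytest.approx(rho_hat)
        assert curve.loglik[1] == max(curve.loglik)
        # profile at the MLE equals the unconstrained maximum
        assert curve.loglik[1] == pytest.approx(fit.loglik, abs=1e-4)

    def test_recovers_generating_correlation(self):
        """On a large simulated dataset the profile argmax tracks the
        unconstrained MLE of rho within grid resolution, and both sit within
        sampling error of the generating rho = 0.721."""
        p = StructuralParams.collapsed(rho=0.721, sigma_y=1.5)
        d = simulate_dataset(
            p, ErrorSpec("normal", rho=0.721, sigma_y=1.5), 7835, seed=31
        )
        fit = fit_mle(d)
        grid = np.arange(0.55, 0.876, 0.025)
        curve = profile_rho(d, grid)
        assert abs(curve.argmax - fit.estimates["rho"]) <= 0.025
        assert abs(curve.argmax - 0.721) <= 3 * fit.se["rho"] + 0.025

    def test_invalid_grid_rejected(self, data_main):
        with pytest.raises(ValueError, match="strictly increasing"):
            profile_rho(data_main, np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="inside"):
            profile_rho(data_main, np.array([-1.0, 0.0]))


class TestExclusionTest:
    def test_no_false_signal_when_exclusion_holds(self, data_main):
        """beta3 = 0 in the generating model: the Wald test does not reject
        wildly (single dataset sanity check; size is tested in the
        simulation suite)."""
        rep = exclusion_test(data_main)
        assert rep.df_num == 1
        assert abs(float(rep.beta3.iloc[0])) < 4 * float(rep.se.iloc[0])

    def test_detects_direct_instrument_effect(self):
        """With beta3 = theta1 = 0.144 the test rejects decisively."""
        p = StructuralParams.collapsed(rho=0.721, sigma_y=1.5, beta3=0.144)
        d = simulate_dataset(
            p, ErrorSpec("normal", rho=0.721, sigma_y=1.5), 7835, seed=13
        )
        rep = exclusion_test(d)
        assert rep.reject
        assert rep.p_value < 1e-4

    def test_collinear_instrument_covariate_rejected(self, data_main):
        X = np.column_stack([data_main.X, data_main.U[:, 0]])
        d = IVDataset(data_main.y, data_main.z, X, data_main.U)
        with pytest.raises(ValueError, match="rank deficient"):
            exclusion_test(d)
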