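"""Observed-data likelihood of the bivariate latent-normal model.

Integrating the latent selection index out of the joint normal model gives a
closed-form per-observation likelihood: the outcome contributes a normal
density with mean ``mu_y = beta1*z + beta2'x (+ beta3'u)`` and SD
``sigma_y``, and the treatment contributes a conditional probit term

    P(z=1 | y) = Phi( (mu_z + rho*(y - mu_y)/sigma_y) / sqrt(1 - rho^2) )

with ``mu_z = theta1'u + theta2'x``.  Only at ``rho = 0`` does this factor
into separate linear and probit fits; otherwise the two equations must be
maximized jointly for ``beta1`` to retain its structural interpretation.

The optimizer works on an unconstrained scale (``atanh rho``, ``log
sigma_y``) with analytic gradients; standard errors come from the inverse
numerical Hessian mapped back by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_fprime

from .data import FitResult, IVDataset, StructuralParams

__all__ = [
    "ProfileCurve",
    "ExclusionTest",
    "loglik",
    "fit_mle",
    "profile_rho",
    "test_exclusion",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ProfileCurve:
    """Profile log-likelihood of the error correlation rho."""

    rho_grid: np.ndarray
    loglik: np.ndarray
    argmax: float

    def __post_init__(self):
        g = np.asarray(self.rho_grid, dtype=float)
        if not (np.diff(g) > 0).all():
            raise ValueError("rho grid must be strictly increasing")
        object.__setattr__(self, "rho_grid", g)
        object.__setattr__(self, "loglik", np.asarray(self.loglik, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho_grid, "loglik": self.loglik})


@dataclass(frozen=True)
class ExclusionTest:
    """Likelihood-based test of the exclusion restriction (H0: beta3 = 0)."""

    beta3: pd.Series
    se: pd.Series
    z_values: pd.Series
    wald: float  # joint Wald statistic, chi-square with df_num df under H0
    f_stat: float  # Wald / df_num, referred to an F distribution
    df_num: int
    p_value: float  # from the chi-square reference
    p_value_f: float
    reject: bool  # at the 0.05 level (chi-square reference)
    fit: FitResult


def _mu(params: StructuralParams, data: IVDataset) -> tuple[np.ndarray, np.ndarray]:
    mu_y = params.beta1 * data.z + data.X @ params.beta2 + data.U @ params.beta3
    mu_z = data.U @ params.theta1 + data.X @ params.theta2
    return mu_y, mu_z


def _loglik_core(y, z, mu_y, mu_z, rho, sigma):
    r = (y - mu_y) / sigma
    s = np.sqrt(1.0 - rho * rho)
    w = (mu_z + rho * r) / s
    ll_y = -np.log(sigma) - 0.5 * r * r - 0.5 * _LOG2PI
    ll_z = np.where(z > 0.5, stats.norm.logcdf(w), stats.norm.logcdf(-w))
    return ll_y + ll_z


def loglik(params: StructuralParams, data: IVDataset) -> float:
    """Observed-data log-likelihood at the given structural parameters."""
    if not abs(params.rho) < 1:
        raise ValueError("|rho| must be < 1 (likelihood undefined at the boundary)")
    if not params.sigma_y > 0:
        raise ValueError("sigma_y must be > 0")
    mu_y, mu_z = _mu(params, data)
    return float(np.sum(_loglik_core(data.y, data.z, mu_y, mu_z, params.rho, params.sigma_y)))


# ---------------------------------------------------------------------------
# internal parameter vector: [beta1, beta2 (p), beta3 (q, if included),
#                             theta1 (q), theta2 (p), atanh(rho), log(sigma)]
# ---------------------------------------------------------------------------


def _param_names(p: int, q: int, with_beta3: bool) -> list[str]:
    names = ["beta1"] + [f"beta2_{j}" for j in range(p)]
    if with_beta3:
        names += [f"beta3_{j}" for j in range(q)]
    names += [f"theta1_{j}" for j in range(q)] + [f"theta2_{j}" for j in range(p)]
    names += ["rho", "sigma_y"]
    return names


def _unpack(vec: np.ndarray, p: int, q: int, with_beta3: bool):
    i = 0
    beta1 = vec[i]; i += 1
    beta2 = vec[i : i + p]; i += p
    if with_beta3:
        beta3 = vec[i : i + q]; i += q
    else:
        beta3 = np.zeros(q)
    theta1 = vec[i : i + q]; i += q
    theta2 = vec[i : i + p]; i += p
    rho = np.tanh(vec[i]); i += 1
    sigma = np.exp(vec[i])
    return beta1, beta2, beta3, theta1, theta2, rho, sigma


def _negloglik_and_grad(vec, data: IVDataset, with_beta3: bool):
    p, q = data.p, data.q
    beta1, beta2, beta3, theta1, theta2, rho, sigma = _unpack(vec, p, q, with_beta3)
    y, z, X, U = data.y, data.z, data.X, data.U
    mu_y = beta1 * z + X @ beta2 + U @ beta3
    mu_z = U @ theta1 + X @ theta2

    r = (y - mu_y) / sigma
    s = np.sqrt(1.0 - rho * rho)
    w = (mu_z + rho * r) / s

    logcdf_w = stats.norm.logcdf(w)
    logcdf_mw = stats.norm.logcdf(-w)
    ll = -np.log(sigma) - 0.5 * r * r - 0.5 * _LOG2PI
    ll = ll + np.where(z > 0.5, logcdf_w, logcdf_mw)

    logpdf_w = -0.5 * w * w - 0.5 * _LOG2PI
    # d/dw of the z-part: inverse Mills ratio with sign by treatment arm
    g = np.where(
        z > 0.5, np.exp(logpdf_w - logcdf_w), -np.exp(logpdf_w - logcdf_mw)
    )

    d_mu_y = r / sigma - g * rho / (sigma * s)
    d_mu_z = g / s
    d_sigma = (r * r - 1.0) / sigma - g * rho * r / (sigma * s)
    d_rho = g * (r / s + w * rho / (s * s))

    grad = np.empty_like(vec)
    i = 0
    grad[i] = d_mu_y @ z; i += 1
    grad[i : i + p] = X.T @ d_mu_y; i += p
    if with_beta3:
        grad[i : i + q] = U.T @ d_mu_y; i += q
    grad[i : i + q] = U.T @ d_mu_z; i += q
    grad[i : i + p] = X.T @ d_mu_z; i += p
    grad[i] = np.sum(d_rho) * (1.0 - rho * rho); i += 1  # chain: atanh scale
    grad[i] = np.sum(d_sigma) * sigma  # chain: log scale

    return -float(np.sum(ll)), -grad


def _start_vector(data: IVDataset, with_beta3: bool, start: StructuralParams | None):
    from . import twostage

    p, q = data.p, data.q
    if start is not None:
        vec = [start.beta1, *start.beta2]
        if with_beta3:
            vec += list(start.beta3)
        vec += [*start.theta1, *start.theta2, np.arctanh(start.rho), np.log(start.sigma_y)]
        return np.array(vec, dtype=float)
    ols = twostage.fit_ols(data)
    fs = twostage.first_stage_probit(data)
    sigma0 = float(np.sqrt(ols.extra["sigma2"]))
    vec = [ols.estimates["beta1"], *[ols.estimates[f"beta2_{j}"] for j in range(p)]]
    if with_beta3:
        vec += [0.0] * q
    vec += [*fs.coef.iloc[:q], *fs.coef.iloc[q:], 0.0, np.log(sigma0)]
    return np.array(vec, dtype=float)


def _result_from_opt(
    data: IVDataset, xopt: np.ndarray, nll: float, converged: bool, with_beta3: bool,
    extra: dict | None = None,
) -> FitResult:
    p, q = data.p, data.q
    names = _param_names(p, q, with_beta3)
    k = len(xopt)

    hess = approx_fprime(
        xopt, lambda v: _negloglik_and_grad(v, data, with_beta3)[1], centered=True
    )
    hess = 0.5 * (hess + hess.T)
    try:
        vcov_t = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov_t = np.linalg.pinv(hess)
        converged = False

    rho = np.tanh(xopt[-2])
    sigma = np.exp(xopt[-1])
    jac = np.ones(k)
    jac[-2] = 1.0 - rho * rho  # d rho / d atanh(rho)
    jac[-1] = sigma  # d sigma / d log(sigma)
    vcov = vcov_t * np.outer(jac, jac)

    est = np.concatenate([xopt[:-2], [rho, sigma]])
    diag = np.diag(vcov)
    se = np.sqrt(np.clip(diag, 0.0, None))
    if (diag < -1e-8).any():
        converged = False
    out = FitResult(
        method="mle" + ("_exclusion" if with_beta3 else ""),
        estimates=pd.Series(est, index=names),
        se=pd.Series(se, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=data.n,
        loglik=-nll,
        converged=converged,
        extra={"vcov_transformed": vcov_t, **(extra or {})},
    )
    return out


def fit_mle(
    data: IVDataset,
    start: StructuralParams | None = None,
    include_instruments_in_outcome: bool = False,
    restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Maximize the observed-data log-likelihood.

    Optimization runs on the unconstrained scale with analytic gradients,
    starting from OLS + probit fits at rho = 0; up to ``restarts`` seeded
    perturbed restarts guard against local optima.  SEs are delta-method
    from the inverse numerical Hessian.  Never raises on non-convergence:
    the returned ``converged`` flag is honest.
    """
    with_beta3 = include_instruments_in_outcome
    x0 = _start_vector(data, with_beta3, start)

    def solve(x_init):
        return optimize.minimize(
            _negloglik_and_grad,
            x_init,
            args=(data, with_beta3),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )

    best = solve(x0)
    rng = np.random.default_rng(seed)
    tries = 1
    while (not best.success or not np.isfinite(best.fun)) and tries <= restarts:
        x_try = x0 + rng.normal(scale=0.1, size=x0.shape)
        res = solve(x_try)
        if np.isfinite(res.fun) and (not np.isfinite(best.fun) or res.fun < best.fun):
            best = res
        tries += 1

    return _result_from_opt(
        data, best.x, best.fun, bool(best.success), with_beta3,
        extra={"n_restarts": tries - 1, "optimizer_message": str(best.message)},
    )


def profile_rho(
    data: IVDataset,
    grid: np.ndarray,
    include_instruments_in_outcome: bool = False,
) -> ProfileCurve:
    """Profile log-likelihood over a grid of rho values.

    For each grid point the remaining parameters are maximized with rho held
    fixed; per-point failures are recorded as NaN rather than aborting the
    curve.
    """
    grid = np.asarray(grid, dtype=float)
    if not ((grid > -1).all() and (grid < 1).all()):
        raise ValueError("rho grid must lie inside (-1, 1)")
    with_beta3 = include_instruments_in_outcome
    x0_full = _start_vector(data, with_beta3, None)

    values = np.full(grid.shape, np.nan)
    x_free = x0_full[:-2]  # all but (atanh rho, log sigma)
    log_sigma = x0_full[-1]
    for i, rho in enumerate(grid):
        a = np.arctanh(rho)

        def nll_fixed(v):
            vec = np.concatenate([v[:-1], [a, v[-1]]])
            f, g = _negloglik_and_grad(vec, data, with_beta3)
            return f, np.concatenate([g[:-2], [g[-1]]])

        res = optimize.minimize(
            nll_fixed,
            np.concatenate([x_free, [log_sigma]]),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if np.isfinite(res.fun):
            values[i] = -res.fun
            # warm-start the neighbouring grid point
            x_free, log_sigma = res.x[:-1], res.x[-1]

    finite = np.isfinite(values)
    argmax = float(grid[finite][np.argmax(values[finite])])
    return ProfileCurve(rho_grid=grid, loglik=values, argmax=argmax)


def test_exclusion(data: IVDataset, level: float = 0.05, seed: int = 0) -> ExclusionTest:
    """Fit the model with the instruments in the outcome equation and test
    H0: beta3 = 0 (per-instrument z statistics and a joint Wald test).

    Identification of beta3 rests on the bivariate-normal error assumption;
    the test is only as trustworthy as that assumption.
    """
    fit = fit_mle(data, include_instruments_in_outcome=True, seed=seed)
    q = data.q
    names = [f"beta3_{j}" for j in range(q)]
    b3 = fit.estimates[names]
    se3 = fit.se[names]
    V = fit.vcov.loc[names, names].to_numpy()
    try:
        wald = float(b3.to_numpy() @ np.linalg.solve(V, b3.to_numpy()))
    except np.linalg.LinAlgError:
        raise ValueError("beta3 covariance singular: instruments collinear in the outcome equation")
    zvals = b3 / se3
    p_chi2 = float(stats.chi2.sf(wald, q))
    f_stat = wald / q
    df_den = data.n - len(fit.estimates)
    p_f = float(stats.f.sf(f_stat, q, df_den))
    return ExclusionTest(
        beta3=b3,
        se=se3,
        z_values=zvals,
        wald=wald,
        f_stat=f_stat,
        df_num=q,
        p_value=p_chi2,
        p_value_f=p_f,
        reject=p_chi2 < level,
        fit=fit,
    )
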