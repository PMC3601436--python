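"""Moment-based estimators: OLS, 2SLS, 2SPS, 2SRI and the first-stage F.

All estimators target ``beta1``, the structural effect of the binary
treatment on the (log-scale) outcome:

* OLS ignores endogeneity and is biased when the treatment is correlated
  with the outcome error.
* 2SLS replaces the treatment with its linear projection on instruments and
  covariates; SEs use the classical IV covariance with residuals formed from
  the *actual* treatment.
* 2SPS (two-stage predictor substitution) fits a probit first stage and
  substitutes the fitted probability for the treatment.
* 2SRI (two-stage residual inclusion) keeps the treatment in the outcome
  equation and adds the probit response residual as a control function.

Second-stage SEs for 2SPS/2SRI account for first-stage estimation through
stacked estimating-equation (sandwich) asymptotics; a nonparametric
bootstrap is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_fprime
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import FitResult, IVDataset

__all__ = [
    "FirstStageFit",
    "FStat",
    "fit_ols",
    "fit_2sls",
    "fit_2sps",
    "fit_2sri",
    "first_stage_F",
]


@dataclass(frozen=True)
class FirstStageFit:
    """Fit of the treatment on (instruments, covariates)."""

    kind: str  # 'linear' or 'probit'
    coef: pd.Series  # theta1 entries first, then theta2
    fitted: np.ndarray  # z-hat (linear) or Phi-hat (probit)
    residuals: np.ndarray  # z - fitted


@dataclass(frozen=True)
class FStat:
    """Partial F for the instruments in the linear first stage."""

    F: float
    df_num: int
    df_den: int
    p_value: float
    weak: bool  # F below the conventional threshold of 10

    def __float__(self) -> float:
        return self.F


def _check_rank(M: np.ndarray, names: list[str], context: str) -> None:
    _, R = np.linalg.qr(M)
    d = np.abs(np.diag(R))
    tol = d.max() * max(M.shape) * np.finfo(float).eps
    if (d < tol).any():
        bad = [names[j] for j in np.flatnonzero(d < tol)]
        raise ValueError(f"{context}: design matrix rank deficient (columns {bad})")


def _check_treatment(z: np.ndarray) -> None:
    if z.min() == z.max():
        raise ValueError("degenerate treatment: all observations in one arm")


def _coef_names(p: int) -> list[str]:
    return ["beta1"] + [f"beta2_{j}" for j in range(p)]


def _fit_linear(W: np.ndarray, y: np.ndarray, names: list[str], method: str) -> FitResult:
    n, k = W.shape
    _check_rank(W, names, method)
    WtW_inv = np.linalg.inv(W.T @ W)
    coef = WtW_inv @ (W.T @ y)
    resid = y - W @ coef
    sigma2 = resid @ resid / (n - k)
    vcov = sigma2 * WtW_inv
    est = pd.Series(coef, index=names)
    se = pd.Series(np.sqrt(np.diag(vcov)), index=names)
    return FitResult(
        method=method,
        estimates=est,
        se=se,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=n,
        extra={"residuals": resid, "sigma2": sigma2},
    )


def fit_ols(data: IVDataset) -> FitResult:
    """Least squares of y on (z, X) with classical homoscedastic SEs."""
    _check_treatment(data.z)
    W = np.column_stack([data.z, data.X])
    return _fit_linear(W, data.y, _coef_names(data.p), "ols")


def first_stage_linear(data: IVDataset) -> FirstStageFit:
    V = np.column_stack([data.U, data.X])
    names = [f"theta1_{j}" for j in range(data.q)] + [f"theta2_{j}" for j in range(data.p)]
    _check_rank(V, names, "first stage")
    coef, *_ = np.linalg.lstsq(V, data.z, rcond=None)
    fitted = V @ coef
    return FirstStageFit("linear", pd.Series(coef, index=names), fitted, data.z - fitted)


def first_stage_probit(data: IVDataset) -> FirstStageFit:
    """Probit MLE of z on (U, X); raises on separation or divergence."""
    _check_treatment(data.z)
    V = np.column_stack([data.U, data.X])
    names = [f"theta1_{j}" for j in range(data.q)] + [f"theta2_{j}" for j in range(data.p)]
    _check_rank(V, names, "probit first stage")
    try:
        res = sm.Probit(data.z, V).fit(disp=0, maxiter=100, tol=1e-8)
    except PerfectSeparationError as e:  # statsmodels' own detection
        raise ValueError(f"probit first stage: perfect separation ({e})") from e
    scale = np.where(V.std(axis=0) > 0, V.std(axis=0), 1.0)
    if not res.mle_retvals.get("converged", True) or np.any(
        np.abs(res.params * scale) > 20
    ):
        raise ValueError(
            "probit first stage did not converge (possible separation: "
            f"max standardized |coef| = {np.abs(res.params * scale).max():.1f})"
        )
    fitted = res.predict()
    return FirstStageFit("probit", pd.Series(res.params, index=names), fitted, data.z - fitted)


def fit_2sls(data: IVDataset) -> FitResult:
    """Two-stage least squares.

    First stage: linear projection of z on (U, X).  Second stage: y on
    (z-hat, X).  The residual variance in the covariance uses the actual z.
    """
    if data.q < 1:
        raise ValueError("2SLS needs at least one instrument")
    _check_treatment(data.z)
    fs = first_stage_linear(data)
    names = _coef_names(data.p)
    What = np.column_stack([fs.fitted, data.X])
    _check_rank(What, names, "2sls second stage")
    WhWh_inv = np.linalg.inv(What.T @ What)
    coef = WhWh_inv @ (What.T @ data.y)
    W_actual = np.column_stack([data.z, data.X])
    resid = data.y - W_actual @ coef
    sigma2 = resid @ resid / (data.n - len(names))
    vcov = sigma2 * WhWh_inv
    est = pd.Series(coef, index=names)
    se = pd.Series(np.sqrt(np.diag(vcov)), index=names)
    fstat = first_stage_F(data)
    return FitResult(
        method="2sls",
        estimates=est,
        se=se,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=data.n,
        extra={"residuals": resid, "sigma2": sigma2, "first_stage": fs, "F": fstat},
    )


def _second_stage_design(kind: str, data: IVDataset, fitted: np.ndarray):
    if kind == "2sps":
        W = np.column_stack([fitted, data.X])
        names = _coef_names(data.p)
    else:  # 2sri
        W = np.column_stack([data.z, data.z - fitted, data.X])
        names = ["beta1", "resid_coef"] + [f"beta2_{j}" for j in range(data.p)]
    return W, names


def _two_step_sandwich(
    kind: str, data: IVDataset, fs_coef: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """Stacked-moment covariance for (probit first stage, OLS second stage).

    Moments: probit score in alpha; second-stage normal equations in gamma
    with the design depending on alpha through Phi(V alpha).  The usual
    block-triangular sandwich A^{-1} B A^{-T} / n follows.
    """
    V = np.column_stack([data.U, data.X])
    n = data.n

    def probit_score(alpha):
        xb = V @ alpha
        phi, Phi = stats.norm.pdf(xb), stats.norm.cdf(xb)
        Phi = np.clip(Phi, 1e-12, 1 - 1e-12)
        lam = (data.z - Phi) * phi / (Phi * (1 - Phi))
        return lam[:, None] * V  # n x dim(alpha)

    def stage2_moments_mean(alpha, g):
        fitted = stats.norm.cdf(V @ alpha)
        W, _ = _second_stage_design(kind, data, fitted)
        e = data.y - W @ g
        return (W * e[:, None]).mean(axis=0)

    fitted = stats.norm.cdf(V @ fs_coef)
    W, _ = _second_stage_design(kind, data, fitted)
    e = data.y - W @ gamma

    g1 = probit_score(fs_coef)
    g2 = W * e[:, None]
    G = np.hstack([g1, g2])
    B = G.T @ G / n

    ka, kg = len(fs_coef), len(gamma)
    A = np.zeros((ka + kg, ka + kg))
    # A11: Jacobian of mean probit score wrt alpha
    A[:ka, :ka] = approx_fprime(
        fs_coef, lambda a: probit_score(a).mean(axis=0), centered=True
    )
    # A21: sensitivity of second-stage moments to the first stage
    A[ka:, :ka] = approx_fprime(
        fs_coef, lambda a: stage2_moments_mean(a, gamma), centered=True
    )
    A[ka:, ka:] = -(W.T @ W) / n
    A_inv = np.linalg.inv(A)
    return (A_inv @ B @ A_inv.T / n)[ka:, ka:]


def _fit_two_stage_probit(
    kind: str,
    data: IVDataset,
    first_stage: str,
    se_method: str,
    n_boot: int,
    seed: int,
) -> FitResult:
    if first_stage == "linear":
        fs = first_stage_linear(data)
    else:
        fs = first_stage_probit(data)
    degenerate_resid = kind == "2sri" and np.allclose(fs.residuals, 0.0, atol=1e-10)
    if degenerate_resid:
        # perfect first stage: the control-function column vanishes; fit
        # without it and report a zero coefficient
        W = np.column_stack([data.z, data.X])
        names = ["beta1"] + [f"beta2_{j}" for j in range(data.p)]
    else:
        W, names = _second_stage_design(kind, data, fs.fitted)
    _check_rank(W, names, f"{kind} second stage")
    coef, *_ = np.linalg.lstsq(W, data.y, rcond=None)
    resid = data.y - W @ coef

    if first_stage == "probit" and se_method == "sandwich":
        vcov = _two_step_sandwich(kind, data, fs.coef.to_numpy(), coef)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, len(coef)))
        for b in range(n_boot):
            idx = rng.integers(0, data.n, size=data.n)
            d = IVDataset(data.y[idx], data.z[idx], data.X[idx], data.U[idx])
            fsb = first_stage_probit(d) if first_stage == "probit" else first_stage_linear(d)
            Wb, _ = _second_stage_design(kind, d, fsb.fitted)
            draws[b], *_ = np.linalg.lstsq(Wb, d.y, rcond=None)
        vcov = np.cov(draws.T)
    else:  # linear first stage: OLS covariance of the second stage (cross-check path)
        sigma2 = resid @ resid / (data.n - len(names))
        vcov = sigma2 * np.linalg.inv(W.T @ W)

    est = pd.Series(coef, index=names)
    se = pd.Series(np.sqrt(np.clip(np.diag(vcov), 0, None)), index=names)
    return FitResult(
        method=kind,
        estimates=est,
        se=se,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=data.n,
        extra={"residuals": resid, "first_stage": fs, "se_method": se_method},
    )


def fit_2sps(
    data: IVDataset,
    first_stage: str = "probit",
    se_method: str = "sandwich",
    n_boot: int = 500,
    seed: int = 0,
) -> FitResult:
    """Two-stage predictor substitution: probit first stage, then OLS of y on
    (Phi-hat, X).  With ``first_stage='linear'`` the point estimates reduce to
    2SLS exactly."""
    return _fit_two_stage_probit("2sps", data, first_stage, se_method, n_boot, seed)


def fit_2sri(
    data: IVDataset,
    first_stage: str = "probit",
    se_method: str = "sandwich",
    n_boot: int = 500,
    seed: int = 0,
) -> FitResult:
    """Two-stage residual inclusion: probit first stage, then OLS of y on
    (z, z - Phi-hat, X).  The control-function coefficient appears as
    ``resid_coef``; with a linear first stage the beta1 point estimate equals
    2SLS."""
    return _fit_two_stage_probit("2sri", data, first_stage, se_method, n_boot, seed)


def first_stage_F(data: IVDataset) -> FStat:
    """Partial F for H0: theta1 = 0 in the linear first stage (Staiger-Stock
    weak-instrument diagnostic; flagged weak below 10)."""
    if data.q == 0:
        raise ValueError("no instruments: F statistic undefined")
    V1 = np.column_stack([data.U, data.X])
    coef1, *_ = np.linalg.lstsq(V1, data.z, rcond=None)
    ssr1 = np.sum((data.z - V1 @ coef1) ** 2)
    coef0, *_ = np.linalg.lstsq(data.X, data.z, rcond=None)
    ssr0 = np.sum((data.z - data.X @ coef0) ** 2)
    df_num = data.q
    df_den = data.n - data.p - data.q
    F = ((ssr0 - ssr1) / df_num) / (ssr1 / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return FStat(F=float(F), df_num=df_num, df_den=df_den, p_value=p, weak=F < 10.0)
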