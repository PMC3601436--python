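"""Core containers and the generative simultaneous-equations model.

The model couples a linear outcome equation with a probit-style selection
equation through correlated errors:

    y_i = beta1 * z_i + beta2' x_i + beta3' u_i + eps_y_i
    z_i = 1(theta1' u_i + theta2' x_i + eps_z_i > 0)

where ``(eps_y, eps_z)`` has mean zero, ``var(eps_z) = 1`` (probit
identification), ``var(eps_y) = sigma_y**2`` and correlation ``rho``.  The
instrument coefficient in the outcome equation, ``beta3``, is zero when the
exclusion restriction holds.  ``rho`` quantifies unobserved selection: a
positive value means unobservables that push a subject into treatment also
push the outcome up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "IVDataset",
    "StructuralParams",
    "ErrorSpec",
    "FitResult",
    "simulate_dataset",
    "make_medicaid_like_fixture",
]


@dataclass(frozen=True)
class IVDataset:
    """Subject-level data for one IV analysis.

    Parameters
    ----------
    y : continuous outcome (log-cost scale), shape (n,).
    z : binary treatment indicator in {0, 1}, shape (n,).
    X : exogenous covariate matrix, shape (n, p); first column constant 1.
    U : instrument matrix, shape (n, q).
    meta : free-form provenance (seed, generating parameters, ...).
    """

    y: np.ndarray
    z: np.ndarray
    X: np.ndarray
    U: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if U.shape[0] == 1 and y.shape[0] > 1:
            U = U.T
        if X.shape[0] == 1 and y.shape[0] > 1:
            X = X.T
        n = y.shape[0]
        if not (z.shape[0] == n and X.shape[0] == n and U.shape[0] == n):
            raise ValueError(
                f"length mismatch: y={n}, z={z.shape[0]}, X={X.shape[0]}, U={U.shape[0]}"
            )
        if not np.isin(z, (0.0, 1.0)).all():
            bad = np.flatnonzero(~np.isin(z, (0.0, 1.0)))[:5]
            raise ValueError(f"treatment must be 0/1; offending rows {bad.tolist()}")
        for name, arr in (("y", y), ("z", z), ("X", X), ("U", U)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing or non-finite values")
        if n <= X.shape[1] + U.shape[1]:
            raise ValueError("need n > p + q for estimability")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "U", U)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.U.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy table (outcome, treatment, x0..., u0...)."""
        d = {"y": self.y, "z": self.z.astype(int)}
        for j in range(self.p):
            d[f"x{j}"] = self.X[:, j]
        for j in range(self.q):
            d[f"u{j}"] = self.U[:, j]
        return pd.DataFrame(d)


@dataclass(frozen=True)
class StructuralParams:
    """Parameters of the simultaneous-equations model.

    ``beta2`` and ``theta2`` run over the columns of ``X`` (the first entry is
    the intercept); ``theta1`` and ``beta3`` run over the columns of ``U``.
    ``rho`` is the error correlation and ``sigma_y`` the outcome error SD
    (the selection error SD is fixed at 1 for identification).
    """

    beta1: float
    beta2: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    rho: float
    sigma_y: float
    beta3: np.ndarray | None = None

    def __post_init__(self):
        beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        theta1 = np.atleast_1d(np.asarray(self.theta1, dtype=float))
        theta2 = np.atleast_1d(np.asarray(self.theta2, dtype=float))
        beta3 = self.beta3
        beta3 = (
            np.zeros_like(theta1)
            if beta3 is None
            else np.atleast_1d(np.asarray(beta3, dtype=float))
        )
        if beta2.shape != theta2.shape:
            raise ValueError("beta2 and theta2 must have equal length (columns of X)")
        if beta3.shape != theta1.shape:
            raise ValueError("beta3 and theta1 must have equal length (columns of U)")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not self.sigma_y > 0:
            raise ValueError("sigma_y must be > 0")
        object.__setattr__(self, "beta2", beta2)
        object.__setattr__(self, "theta1", theta1)
        object.__setattr__(self, "theta2", theta2)
        object.__setattr__(self, "beta3", beta3)

    @classmethod
    def collapsed(
        cls,
        beta1: float = -0.793,
        theta1: float = 0.144,
        rho: float = 0.721,
        sigma_y: float = 1.0,
        beta2: float = 1.0,
        theta2: float = 1.0,
        beta3: float = 0.0,
    ) -> "StructuralParams":
        """Univariate design with one collapsed covariate and one collapsed
        instrument, both unit-variance, and zero intercepts.  Defaults mirror
        the antipsychotic cost study's fitted effects (treatment effect
        -0.793 on the log scale, instrument effect 0.144, selection
        correlation 0.721)."""
        return cls(
            beta1=beta1,
            beta2=np.array([0.0, beta2]),
            theta1=np.array([theta1]),
            theta2=np.array([0.0, theta2]),
            rho=rho,
            sigma_y=sigma_y,
            beta3=np.array([beta3]),
        )

    def with_(self, **kw) -> "StructuralParams":
        return replace(self, **kw)


# gamma-error construction: right-skewed gamma marginals coupled by a
# Gaussian copula; shape 0.5 gives strong visible skew (skewness ~2.8)
_GAMMA_SHAPE = 0.5


@lru_cache(maxsize=32)
def _copula_corr_for_target(target: float, shape: float) -> float:
    """Gaussian-copula correlation giving the requested Pearson correlation
    between (possibly sign-flipped) standardized gamma marginals."""
    from scipy import optimize, stats as sps

    nodes, weights = np.polynomial.hermite_e.hermegauss(96)
    w = weights / np.sqrt(2.0 * np.pi)

    def h(x):  # standardized gamma quantile transform
        u = np.clip(sps.norm.cdf(x), 1e-15, 1 - 1e-15)
        return (sps.gamma.ppf(u, shape) - shape) / np.sqrt(shape)

    hx = h(nodes)

    def pearson(r):
        # E[h(n1) h(n2)] over the bivariate normal copula by 2-D quadrature
        inner = np.array(
            [np.sum(w * h(r * x + np.sqrt(1.0 - r * r) * nodes)) for x in nodes]
        )
        return float(np.sum(w * hx * inner))

    return float(
        optimize.brentq(lambda r: pearson(r) - target, -0.999, 0.999, xtol=1e-10)
    )


@dataclass(frozen=True)
class ErrorSpec:
    """How to draw the error pair (eps_y, eps_z).

    family : 'normal', 't7' (bivariate t, 7 df, variance-matched) or 'gamma'
        (common-shock construction from independent gamma variables).
    rho : target correlation; sigma_y : target SD of eps_y.  var(eps_z) = 1
    always.
    """

    family: str
    rho: float
    sigma_y: float

    def __post_init__(self):
        if self.family not in ("normal", "t7", "gamma"):
            raise ValueError(f"unknown error family {self.family!r}")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not self.sigma_y > 0:
            raise ValueError("sigma_y must be > 0")

    def covariance(self) -> np.ndarray:
        s, r = self.sigma_y, self.rho
        return np.array([[s * s, r * s], [r * s, 1.0]])

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (eps_y, eps_z), each length n, with the target moments."""
        cov = self.covariance()
        if self.family == "normal":
            e = rng.multivariate_normal(np.zeros(2), cov, size=n)
            return e[:, 0], e[:, 1]
        if self.family == "t7":
            # multivariate t = N(0, Sigma) / sqrt(chi2_df / df); its variance
            # is Sigma * df/(df-2), so shrink the scale matrix by (df-2)/df
            # to keep var(eps_z) = 1 exactly
            df = 7.0
            g = rng.multivariate_normal(np.zeros(2), cov * (df - 2.0) / df, size=n)
            w = np.sqrt(rng.chisquare(df, size=n) / df)
            e = g / w[:, None]
            return e[:, 0], e[:, 1]
        # gamma: gamma(shape) marginals joined by a Gaussian copula whose
        # correlation is root-found so the Pearson correlation of the error
        # pair hits rho exactly; margins standardized to the target moments
        from scipy import stats as sps

        k = _GAMMA_SHAPE
        r = _copula_corr_for_target(self.rho, k)
        g = rng.multivariate_normal(np.zeros(2), [[1.0, r], [r, 1.0]], size=n)
        u = np.clip(sps.norm.cdf(g), 1e-15, 1 - 1e-15)
        gy = (sps.gamma.ppf(u[:, 0], k) - k) / np.sqrt(k)
        gz = (sps.gamma.ppf(u[:, 1], k) - k) / np.sqrt(k)
        return self.sigma_y * gy, gz

    def description(self) -> dict:
        d = {"family": self.family, "rho": self.rho, "sigma_y": self.sigma_y}
        if self.family == "gamma":
            d["gamma_shape"] = _GAMMA_SHAPE
            d["copula_corr"] = _copula_corr_for_target(self.rho, _GAMMA_SHAPE)
        return d


@dataclass(frozen=True)
class FitResult:
    """Estimates from one fitting method.

    estimates/se are aligned named Series; vcov is the full covariance matrix
    on the natural parameter scale.
    """

    method: str
    estimates: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    loglik: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.estimates.index) != list(self.se.index):
            raise ValueError("estimates and se must share names")
        if (np.asarray(self.se) < -1e-12).any():
            raise ValueError("standard errors must be nonnegative")

    @property
    def beta1(self) -> float:
        return float(self.estimates["beta1"])

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        h = norm.ppf(0.5 + level / 2.0) * self.se
        return pd.DataFrame(
            {"lower": self.estimates - h, "upper": self.estimates + h}
        )

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        z = self.estimates / self.se.replace(0.0, np.nan)
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def simulate_dataset(
    params: StructuralParams,
    errors: ErrorSpec,
    n: int,
    seed: int | np.random.Generator,
) -> IVDataset:
    """Draw one dataset from the simultaneous-equations model.

    Covariates beyond the intercept and all instrument columns are drawn as
    independent standard normals (the collapsed, unit-variance design used in
    the simulation study); errors follow ``errors``.  Deterministic given the
    seed.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (
        np.isclose(errors.rho, params.rho) and np.isclose(errors.sigma_y, params.sigma_y)
    ):
        raise ValueError("ErrorSpec targets must match StructuralParams (rho, sigma_y)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, q = params.beta2.shape[0], params.theta1.shape[0]
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    U = np.column_stack([rng.standard_normal(n) for _ in range(q)])
    eps_y, eps_z = errors.draw(n, rng)
    latent = U @ params.theta1 + X @ params.theta2 + eps_z
    z = (latent > 0).astype(float)
    y = params.beta1 * z + X @ params.beta2 + U @ params.beta3 + eps_y
    meta = {"generator": "simulate_dataset", "errors": errors.description(), "n": n}
    return IVDataset(y=y, z=z, X=X, U=U, meta=meta)


def make_medicaid_like_fixture(
    n: int = 1000,
    seed: int = 0,
    params: StructuralParams | None = None,
) -> IVDataset:
    """Synthetic dataset with the *structure* of a state Medicaid claims design.

    Real claims data of this kind are not public; this fixture emulates their shape
    only: covariates are an intercept, region dummies and a continuous
    standardized age, and each instrument column is the product of a binary
    drug-availability indicator and a region dummy.  Outcome and treatment
    are generated from the simultaneous-equations model with normal errors.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    n_regions = 4  # ref region + 3 dummies
    region = rng.integers(0, n_regions, size=n)
    dummies = np.column_stack([(region == k + 1).astype(float) for k in range(n_regions - 1)])
    age = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), dummies, age])

    # availability of two drugs varies by region and a within-region lottery,
    # mimicking staggered local uptake after approval
    avail = np.column_stack(
        [
            (rng.random(n) < 0.4 + 0.1 * region).astype(float),
            (rng.random(n) < 0.7 - 0.1 * region).astype(float),
        ]
    )
    U = np.column_stack(
        [avail[:, d] * dummies[:, k] for d in range(2) for k in range(n_regions - 1)]
    )

    if params is None:
        p = X.shape[1]
        q = U.shape[1]
        params = StructuralParams(
            beta1=-0.793,
            beta2=np.concatenate([[0.0], np.full(p - 1, 0.3)]),
            theta1=np.full(q, 0.4),
            theta2=np.concatenate([[0.0], np.full(p - 1, 0.3)]),
            rho=0.721,
            sigma_y=1.2,
        )
    errors = ErrorSpec("normal", rho=params.rho, sigma_y=params.sigma_y)
    eps_y, eps_z = errors.draw(n, rng)
    latent = U @ params.theta1 + X @ params.theta2 + eps_z
    z = (latent > 0).astype(float)
    y = params.beta1 * z + X @ params.beta2 + U @ params.beta3 + eps_y
    meta = {"generator": "make_medicaid_like_fixture", "seed": seed, "n": n}
    return IVDataset(y=y, z=z, X=X, U=U, meta=meta)
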