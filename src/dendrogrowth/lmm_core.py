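"""Linear mixed-effects models with tree-level random effects and AR(1) errors.

This module provides the likelihood machinery shared by the climate-growth
and growth-trend analyses.  The model for the response vector of tree *i* is

    y_i = X_i beta + Z_i b_i + eps_i,        b_i ~ N(0, G),
    eps_i ~ N(0, sigma^2 C_i(phi)),

where ``C_i(phi)`` is the AR(1) correlation matrix with entries
``phi ** |year_s - year_t|`` (calendar-year spacing, so gaps decay
correctly) and ``G`` is the tree-level random-effect covariance (diagonal by
default; unstructured available for up to two effects).  Estimation is by
maximum likelihood (ML) or restricted maximum likelihood (REML) on the
marginal Gaussian likelihood: the fixed effects are profiled out by
generalized least squares and the residual variance is profiled in closed
form, leaving a low-dimensional optimisation over transformed variance
parameters (log relative SDs, atanh phi).

Numerically, the AR(1) structure of each tree is removed by an exact O(m)
whitening transform (the process is Markov), after which the random-effect
contribution is handled by the Woodbury identity, so one likelihood
evaluation costs O(N q^2) for N stacked observations and q random effects.
This is what makes the exhaustive 2^15 model enumeration in
:mod:`dendrogrowth.climate_growth` tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"

__all__ = [
    "ModelSpec",
    "LMMParams",
    "GroupedData",
    "LMMFit",
    "DiagnosticsReport",
    "marginal_loglik",
    "fit_lmm",
    "information_criteria",
    "diagnostics",
    "random_effects",
    "significance_stars",
]


# ---------------------------------------------------------------------------
# model specification and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of a mixed model.

    ``fixed`` lists the fixed-effect columns (the intercept is implicit and
    always included).  ``random`` lists the columns carrying tree-level
    random slopes; a random intercept is always included.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    random_cov: str = "diagonal"  # {"diagonal", "unstructured"}
    ar1: bool = True

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicate fixed-effect labels")
        bad = set(self.random) - set(self.fixed)
        if bad:
            raise ValueError(f"random effects must be a subset of fixed effects: {sorted(bad)}")
        if self.random_cov not in ("diagonal", "unstructured"):
            raise ValueError(f"unknown random_cov {self.random_cov!r}")
        if self.random_cov == "unstructured" and len(self.random) + 1 > 2:
            raise ValueError("unstructured G is only supported for up to 2 random effects")

    @property
    def x_names(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.fixed

    @property
    def z_names(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.random


@dataclass
class LMMParams:
    """Explicit parameter vector for direct likelihood evaluation."""

    beta: np.ndarray
    re_sd: np.ndarray
    phi: float
    sigma: float
    re_corr: float | None = None


@dataclass
class GroupedData:
    """Stacked per-tree design: rows sorted by (group, year).

    ``starts`` holds the first stacked index of every group, which drives the
    vectorised per-group reductions used by the likelihood.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    years: np.ndarray
    group: np.ndarray          # integer codes, contiguous blocks
    starts: np.ndarray         # first index of each group
    group_ids: list
    x_names: tuple[str, ...]
    z_names: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return self.starts.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: ModelSpec,
                   group_col: str = "tree_id", year_col: str = "year") -> "GroupedData":
        need = [group_col, year_col, spec.response, *spec.fixed]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"data frame lacks columns {missing}")
        df = df[need].dropna()
        df = df.sort_values([group_col, year_col], kind="mergesort").reset_index(drop=True)
        codes, group_ids = pd.factorize(df[group_col], sort=True)
        years = df[year_col].to_numpy(dtype=np.int64)
        # strictly increasing years within each group
        same = np.flatnonzero(np.diff(codes) == 0)
        if np.any(years[same + 1] <= years[same]):
            raise ValueError("years must be strictly increasing within each group "
                             "(duplicate tree/year rows?)")
        n = len(df)
        X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in spec.fixed])
        zcols = [0] + [1 + spec.fixed.index(c) for c in spec.random]
        Z = X[:, zcols].copy()
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        return cls(y=df[spec.response].to_numpy(float), X=X, Z=Z, years=years,
                   group=codes.astype(np.int64), starts=starts, group_ids=list(group_ids),
                   x_names=spec.x_names, z_names=spec.z_names)

    def subset_columns(self, x_names: tuple[str, ...], z_names: tuple[str, ...]) -> "GroupedData":
        """View with a subset of fixed/random columns (for model enumeration)."""
        xi = [self.x_names.index(c) for c in x_names]
        zi = [self.x_names.index(c) for c in z_names]
        return replace(self, X=self.X[:, xi], Z=self.X[:, zi],
                       x_names=tuple(x_names), z_names=tuple(z_names))


@dataclass
class LMMFit:
    spec: ModelSpec
    method: str
    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov_beta: np.ndarray
    re_sd: pd.Series
    re_corr: float | None
    phi: float
    sigma: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    k_params: int
    re_sd_se: pd.Series | None = None
    phi_se: float | None = None
    sigma_se: float | None = None
    theta_opt: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Fixed effects with SE, p and stars; random-effect SDs in brackets."""
        rows = []
        for name in self.beta.index:
            rows.append({
                "term": name,
                "estimate": self.beta[name],
                "se": self.se[name],
                "p": self.pvalues[name],
                "stars": significance_stars(self.pvalues[name]),
                "re_sd": self.re_sd.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# AR(1) whitening
# ---------------------------------------------------------------------------

def _ar1_rho(data: GroupedData, phi: float) -> np.ndarray:
    """Lag-correlation of each row with its predecessor (0 at group starts)."""
    n = data.n_obs
    delta = np.zeros(n, dtype=np.int64)
    delta[1:] = data.years[1:] - data.years[:-1]
    delta[data.starts] = 0
    if phi == 0.0:
        return np.zeros(n)
    rho = np.sign(phi) ** (delta % 2) * np.abs(phi) ** delta
    rho[data.starts] = 0.0
    return rho


def _whiten(M: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Apply the exact AR(1) whitening transform row-block-wise.

    For x with corr(x_j, x_{j-1}) = rho_j, e_j = (x_j - rho_j x_{j-1}) /
    sqrt(1 - rho_j^2) has identity correlation; rho = 0 at group starts.
    """
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    prev = np.empty_like(M)
    prev[1:] = M[:-1]
    prev[0] = 0.0
    d = np.sqrt(1.0 - rho * rho)
    out = (M - rho[:, None] * prev) / d[:, None]
    return out[:, 0] if one_d else out


def _logdet_C(rho: np.ndarray) -> float:
    return float(np.log1p(-rho * rho).sum())


def _group_reduce(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum rows of ``arr`` within each contiguous group block."""
    return np.add.reduceat(arr, starts, axis=0)


def _re_chol(gammas: np.ndarray, corr: float | None) -> np.ndarray:
    """Cholesky factor of the (relative) random-effect covariance."""
    q = gammas.size
    if corr is None or q == 1:
        return np.diag(gammas)
    if q != 2:
        raise ValueError("correlated random effects supported for q = 2 only")
    if not -1.0 < corr < 1.0:
        raise ValueError("random-effect correlation must lie in (-1, 1)")
    L = np.array([[gammas[0], 0.0],
                  [gammas[1] * corr, gammas[1] * np.sqrt(1.0 - corr ** 2)]])
    return L


# ---------------------------------------------------------------------------
# profiled likelihood quantities
# ---------------------------------------------------------------------------

def _phi_level_q1(data: GroupedData, phi: float, cache: dict | None):
    """Whitened cross-products for the random-intercept-only model.

    These depend on phi but not on the random-intercept scale, so they are
    cached per phi: during optimisation every evaluation that only moves
    the variance-ratio coordinate reuses them, which is what keeps the
    exhaustive model enumeration fast.
    """
    key = None
    if cache is not None:
        key = round(float(phi), 14)
        hit = cache.get(key)
        if hit is not None:
            return hit
    rho = _ar1_rho(data, phi)
    Xw = _whiten(data.X, rho)
    yw = _whiten(data.y, rho)
    zw = _whiten(data.Z[:, 0], rho)
    starts = data.starts
    val = (Xw.T @ Xw, Xw.T @ yw, float(yw @ yw), _logdet_C(rho),
           _group_reduce(zw * zw, starts),
           _group_reduce(zw[:, None] * Xw, starts),
           _group_reduce(zw * yw, starts))
    if cache is not None:
        if len(cache) > 8:
            cache.clear()
        cache[key] = val
    return val


def _w_metric_q1(data: GroupedData, gamma: float, phi: float,
                 cache: dict | None):
    XtX, Xty, yty, logdetC, z2, zx, zy = _phi_level_q1(data, phi, cache)
    g2 = gamma * gamma
    s = 1.0 + g2 * z2
    c = g2 / s
    XtMX = XtX - (zx * c[:, None]).T @ zx
    XtMy = Xty - zx.T @ (c * zy)
    ytMy = yty - float((c * zy * zy).sum())
    return XtMX, XtMy, ytMy, logdetC + float(np.log(s).sum())


def _w_metric_quantities(data: GroupedData, gammas: np.ndarray,
                         re_corr: float | None, phi: float,
                         cache: dict | None = None):
    """Return (XtWX, XtWy, ytWy, logdetW) in the W = C + Z Gr Z' metric.

    Gr is the *relative* random-effect covariance (G / sigma^2).  All
    products are computed through whitening + Woodbury, never forming W.
    """
    if data.Z.shape[1] == 1 and re_corr is None:
        return _w_metric_q1(data, float(gammas[0]), phi, cache)
    rho = _ar1_rho(data, phi)
    Xw = _whiten(data.X, rho)
    yw = _whiten(data.y, rho)
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    yty = float(yw @ yw)
    logdet = _logdet_C(rho)
    q = data.Z.shape[1]
    if np.all(gammas == 0.0):
        return XtX, Xty, yty, logdet
    L = _re_chol(gammas, re_corr)
    A = _whiten(data.Z, rho) @ L  # A A' = Z Gr Z' in the whitened metric
    starts = data.starts
    p = Xw.shape[1]
    AtA = _group_reduce((A[:, :, None] * A[:, None, :]).reshape(-1, q * q), starts)
    AtX = _group_reduce((A[:, :, None] * Xw[:, None, :]).reshape(-1, q * p), starts)
    Aty = _group_reduce(A * yw[:, None], starts)
    eye = np.eye(q)
    for i in range(data.n_groups):
        S = eye + AtA[i].reshape(q, q)
        c, low = cho_factor(S, lower=True)
        logdet += 2.0 * float(np.log(np.diag(c)).sum())
        ax_i = AtX[i].reshape(q, p)
        bx = cho_solve((c, low), ax_i)
        by = cho_solve((c, low), Aty[i])
        XtX -= ax_i.T @ bx
        Xty -= ax_i.T @ by
        yty -= float(Aty[i] @ by)
    return XtX, Xty, yty, logdet


def _gls(XtWX, XtWy):
    try:
        c, low = cho_factor(XtWX)
        beta = cho_solve((c, low), XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    return beta


_LOG2PI = float(np.log(2.0 * np.pi))


def _profiled_nll(theta: np.ndarray, data: GroupedData, method: str,
                  ar1: bool, q: int, unstructured: bool,
                  cache: dict | None = None):
    """Negative profiled log-likelihood over transformed variance params."""
    gammas = np.exp(theta[:q])
    pos = q
    re_corr = None
    if unstructured and q == 2:
        re_corr = float(np.tanh(theta[pos]))
        pos += 1
    phi = float(np.tanh(theta[pos])) if ar1 else 0.0
    XtWX, XtWy, ytWy, logdetW = _w_metric_quantities(data, gammas, re_corr, phi,
                                                     cache)
    beta = _gls(XtWX, XtWy)
    rss = max(ytWy - float(XtWy @ beta), 1e-300)
    n = data.n_obs
    p = data.X.shape[1]
    if method == "ML":
        nll = 0.5 * (n * _LOG2PI + n * np.log(rss / n) + logdetW + n)
    else:
        sign, ld = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e10
        nll = 0.5 * ((n - p) * (_LOG2PI + np.log(rss / (n - p)) + 1.0) + logdetW + ld)
    if not np.isfinite(nll):
        return 1e10
    return float(nll)


# ---------------------------------------------------------------------------
# direct (unprofiled) marginal likelihood — the spec'd evaluation entry point
# ---------------------------------------------------------------------------

def marginal_loglik(spec: ModelSpec, data: GroupedData, params: LMMParams,
                    method: str = "ML") -> float:
    """Marginal Gaussian log-likelihood at explicit parameter values.

    ML evaluates the density of the stacked response with per-tree covariance
    ``V_i = Z_i G Z_i' + sigma^2 C_i(phi)`` at ``params.beta``.  REML is
    independent of beta: it uses the GLS estimate internally and equals
    ``loglik_ML(beta_GLS) - 1/2 log|X' V^-1 X| + p/2 log(2 pi)``.
    """
    re_sd = np.asarray(params.re_sd, dtype=float)
    if np.any(re_sd < 0):
        raise ValueError("random-effect SDs must be nonnegative")
    if not -1.0 < params.phi < 1.0:
        raise ValueError("|phi| must be < 1")
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if re_sd.size != data.Z.shape[1]:
        raise ValueError("re_sd length must match the number of random effects")
    sigma = float(params.sigma)
    gammas = re_sd / sigma
    XtWX, XtWy, ytWy, logdetW = _w_metric_quantities(data, gammas, params.re_corr, params.phi)
    n = data.n_obs
    p = data.X.shape[1]

    def _ll_at(beta):
        beta = np.asarray(beta, dtype=float)
        rss = ytWy - 2.0 * float(XtWy @ beta) + float(beta @ XtWX @ beta)
        return -0.5 * (n * _LOG2PI + n * np.log(sigma ** 2) + logdetW + rss / sigma ** 2)

    if method == "ML":
        return float(_ll_at(params.beta))
    if method != "REML":
        raise ValueError(f"unknown method {method!r}")
    beta_gls = _gls(XtWX, XtWy)
    sign, ld = np.linalg.slogdet(XtWX / sigma ** 2)
    if sign <= 0:
        raise ValueError("X' V^-1 X is not positive definite")
    return float(_ll_at(beta_gls) - 0.5 * ld + 0.5 * p * _LOG2PI)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_GAMMA_BOUNDS = (-10.0, 5.0)
_ATANH_BOUNDS = (-6.0, 6.0)
_SINGULAR_GAMMA = 2e-4  # below this relative SD, report the component as 0


def _finish_fit(spec, data, method, theta, converged, compute_var_se, notes):
    q = data.Z.shape[1]
    unstructured = spec.random_cov == "unstructured" and q == 2
    gammas = np.exp(theta[:q])
    pos = q
    re_corr = float(np.tanh(theta[pos])) if unstructured else None
    if unstructured:
        pos += 1
    phi = float(np.tanh(theta[pos])) if spec.ar1 else 0.0
    XtWX, XtWy, ytWy, logdetW = _w_metric_quantities(data, gammas, re_corr, phi)
    beta = _gls(XtWX, XtWy)
    rss = max(ytWy - float(XtWy @ beta), 1e-300)
    n, p = data.n_obs, data.X.shape[1]
    sigma2 = rss / n if method == "ML" else rss / (n - p)
    sigma = float(np.sqrt(sigma2))
    loglik = -_profiled_nll(theta, data, method, spec.ar1, q, unstructured)
    try:
        cov_beta = sigma2 * np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        notes = notes + ["rank-deficient fixed-effect design: "
                         "pseudo-inverse covariance"]
        cov_beta = sigma2 * np.linalg.pinv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    df = max(n - data.n_groups - p, 1)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    re_sd = gammas * sigma
    singular = gammas <= _SINGULAR_GAMMA
    if np.any(singular):
        notes = notes + [f"singular random-effect SD reported as 0: "
                         f"{[data.z_names[i] for i in np.flatnonzero(singular)]}"]
        re_sd = np.where(singular, 0.0, re_sd)
    k = p + q + (1 if unstructured else 0) + (1 if spec.ar1 else 0) + 1
    fit = LMMFit(
        spec=spec, method=method,
        beta=pd.Series(beta, index=list(data.x_names)),
        se=pd.Series(se, index=list(data.x_names)),
        pvalues=pd.Series(pvals, index=list(data.x_names)),
        cov_beta=cov_beta,
        re_sd=pd.Series(re_sd, index=list(data.z_names)),
        re_corr=re_corr, phi=phi, sigma=sigma, loglik=float(loglik),
        n_obs=n, n_groups=data.n_groups, converged=converged, k_params=k,
        notes=notes,
    )
    if compute_var_se:
        _attach_variance_se(fit, data, method)
    return fit


def _attach_variance_se(fit: LMMFit, data: GroupedData, method: str) -> None:
    """Wald SEs for (re_sd, phi, sigma) from the numerical Hessian of the
    log-likelihood on the transformed scale (log SD, atanh phi, log sigma),
    with beta profiled out; delta method back to the natural scale."""
    q = data.Z.shape[1]
    spec = fit.spec
    unstructured = fit.re_corr is not None

    def nll_u(u):
        re_sd = np.exp(u[:q])
        pos = q
        corr = float(np.tanh(u[pos])) if unstructured else None
        if unstructured:
            pos += 1
        phi = float(np.tanh(u[pos])) if spec.ar1 else 0.0
        pos += 1 if spec.ar1 else 0
        sigma = float(np.exp(u[pos]))
        gammas = re_sd / sigma
        XtWX, XtWy, ytWy, logdetW = _w_metric_quantities(data, gammas, corr, phi)
        beta = _gls(XtWX, XtWy)
        rss = ytWy - 2 * float(XtWy @ beta) + float(beta @ XtWX @ beta)
        n, p = data.n_obs, data.X.shape[1]
        ll = -0.5 * (n * _LOG2PI + n * np.log(sigma ** 2) + logdetW + rss / sigma ** 2)
        if method == "REML":
            sign, ld = np.linalg.slogdet(XtWX / sigma ** 2)
            ll += -0.5 * ld + 0.5 * p * _LOG2PI
        return -ll

    u0 = []
    u0.extend(np.log(np.maximum(fit.re_sd.to_numpy(), 1e-8)))
    if unstructured:
        u0.append(np.arctanh(np.clip(fit.re_corr, -0.999, 0.999)))
    if spec.ar1:
        u0.append(np.arctanh(np.clip(fit.phi, -0.999, 0.999)))
    u0.append(np.log(fit.sigma))
    u0 = np.asarray(u0)
    m = u0.size
    h = 1e-3
    try:
        H = np.empty((m, m))
        f0 = nll_u(u0)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h
                ej = np.zeros(m); ej[j] = h
                if i == j:
                    H[i, i] = (nll_u(u0 + ei) - 2 * f0 + nll_u(u0 - ei)) / h ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll_u(u0 + ei + ej) - nll_u(u0 + ei - ej)
                        - nll_u(u0 - ei + ej) + nll_u(u0 - ei - ej)
                    ) / (4 * h ** 2)
        cov = np.linalg.pinv(H)
        sd_u = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:  # pragma: no cover - defensive
        sd_u = np.full(m, np.nan)
    re_sd_se = sd_u[:q] * fit.re_sd.to_numpy()
    pos = q + (1 if unstructured else 0)
    fit.re_sd_se = pd.Series(re_sd_se, index=fit.re_sd.index)
    if spec.ar1:
        fit.phi_se = float(sd_u[pos] * (1.0 - fit.phi ** 2))
        pos += 1
    fit.sigma_se = float(sd_u[-1] * fit.sigma)


def fit_lmm(spec: ModelSpec, data: GroupedData, method: str = "REML",
            start: np.ndarray | None = None, n_restarts: int = 0,
            compute_var_se: bool = True, tol: float = 1e-10) -> LMMFit:
    """Fit the mixed model by ML or REML.

    Variance parameters are optimised on a transformed scale
    (log relative SD, atanh correlation/phi) by L-BFGS-B with
    finite-difference gradients; beta and sigma are profiled analytically.
    ``start`` warm-starts the optimiser (used heavily by the exhaustive
    model enumeration).  Non-convergence yields ``converged=False`` plus a
    warning, never an exception.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}")
    q = data.Z.shape[1]
    p = data.X.shape[1]
    unstructured = spec.random_cov == "unstructured" and q == 2
    n_theta = q + (1 if unstructured else 0) + (1 if spec.ar1 else 0)
    if data.n_groups < 2:
        raise ValueError("at least 2 groups (trees) are required")
    if data.n_obs <= p + n_theta + 1:
        raise ValueError("more parameters than observations")

    if start is None:
        theta0 = np.full(n_theta, np.log(0.5))
        if unstructured:
            theta0[q] = 0.0
        if spec.ar1:
            theta0[-1] = np.arctanh(0.3)
    else:
        theta0 = np.asarray(start, dtype=float)
        if theta0.size != n_theta:
            raise ValueError("start vector has wrong length")

    bounds = [_LOG_GAMMA_BOUNDS] * q
    if unstructured:
        bounds.append(_ATANH_BOUNDS)
    if spec.ar1:
        bounds.append(_ATANH_BOUNDS)

    cache: dict | None = {} if (q == 1 and not unstructured) else None
    args = (data, method, spec.ar1, q, unstructured, cache)
    best = optimize.minimize(_profiled_nll, theta0, args=args, method="L-BFGS-B",
                             bounds=bounds, options={"ftol": tol, "gtol": 1e-7,
                                                     "maxiter": 500})
    rng = np.random.default_rng(0)
    for _ in range(n_restarts):
        t0 = theta0 + rng.normal(scale=0.7, size=n_theta)
        t0 = np.clip(t0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(_profiled_nll, t0, args=args, method="L-BFGS-B",
                                bounds=bounds, options={"ftol": tol, "gtol": 1e-7,
                                                        "maxiter": 500})
        if res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        # L-BFGS-B line searches can fail on finite-difference gradients
        # very close to the optimum; a simplex polish settles those cases
        res = optimize.minimize(_profiled_nll, best.x, args=args,
                                method="Nelder-Mead",
                                options={"fatol": 1e-9, "xatol": 1e-7,
                                         "maxiter": 400})
        if res.fun <= best.fun + 1e-9:
            best = res
            converged = bool(res.success)
    if not converged:
        logger.warning("LMM optimiser did not converge: %s", best.message)
    fit = _finish_fit(spec, data, method, best.x, converged, compute_var_se, [])
    fit.theta_opt = best.x
    return fit


def information_criteria(fit: LMMFit) -> tuple[float, float]:
    """(AIC, BIC) with n = total observations."""
    k = fit.k_params
    if k <= 0:
        raise ValueError("parameter count must be positive")
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * np.log(fit.n_obs)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# diagnostics and BLUPs
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    vif: pd.Series
    shapiro_w: float
    shapiro_p: float
    normality_flag: bool
    hetero_slope: float
    hetero_p: float
    hetero_flag: bool
    lag1_autocorr: float

    def to_text(self) -> str:
        lines = ["model diagnostics",
                 "-----------------",
                 "variance inflation factors:"]
        for name, v in self.vif.items():
            lines.append(f"  {name}: {v:.3g}" + ("  <- collinear" if not np.isfinite(v) or v > 10 else ""))
        lines.append(f"Shapiro-Wilk on normalized residuals: W={self.shapiro_w:.4f}, "
                     f"p={self.shapiro_p:.3g}" + ("  <- non-normal" if self.normality_flag else ""))
        lines.append(f"|residual| vs fitted slope: {self.hetero_slope:.4g} "
                     f"(p={self.hetero_p:.3g})" + ("  <- heteroscedastic" if self.hetero_flag else ""))
        lines.append(f"lag-1 autocorrelation of whitened residuals: {self.lag1_autocorr:.4f}")
        return "\n".join(lines)


def _group_cov_chol(fit: LMMFit, data: GroupedData, lo: int, hi: int) -> np.ndarray:
    yrs = data.years[lo:hi]
    d = np.abs(yrs[:, None] - yrs[None, :])
    phi = fit.phi
    C = np.sign(phi) ** (d % 2) * np.abs(phi) ** d if phi != 0 else np.eye(hi - lo)
    if phi != 0:
        np.fill_diagonal(C, 1.0)
    re_sd = fit.re_sd.to_numpy()
    if fit.re_corr is not None and re_sd.size == 2:
        R = np.array([[1.0, fit.re_corr], [fit.re_corr, 1.0]])
        G = np.outer(re_sd, re_sd) * R
    else:
        G = np.diag(re_sd ** 2)
    Z = data.Z[lo:hi]
    V = Z @ G @ Z.T + fit.sigma ** 2 * C
    return cholesky(V, lower=True), G, Z, C


def _whitened_residuals(fit: LMMFit, data: GroupedData) -> np.ndarray:
    r = data.y - data.X @ fit.beta.to_numpy()
    out = np.empty_like(r)
    bounds = np.r_[data.starts, data.n_obs]
    for i in range(data.n_groups):
        lo, hi = bounds[i], bounds[i + 1]
        L, *_ = _group_cov_chol(fit, data, lo, hi)
        out[lo:hi] = solve_triangular(L, r[lo:hi], lower=True)
    return out


def random_effects(fit: LMMFit, data: GroupedData) -> pd.DataFrame:
    """Empirical BLUPs b_i = G Z_i' V_i^-1 (y_i - X_i beta), one row per tree."""
    r = data.y - data.X @ fit.beta.to_numpy()
    bounds = np.r_[data.starts, data.n_obs]
    rows = []
    for i in range(data.n_groups):
        lo, hi = bounds[i], bounds[i + 1]
        L, G, Z, _ = _group_cov_chol(fit, data, lo, hi)
        u = solve_triangular(L, r[lo:hi], lower=True)
        u = solve_triangular(L.T, u, lower=False)
        rows.append(G @ Z.T @ u)
    return pd.DataFrame(rows, index=data.group_ids, columns=list(data.z_names))


def diagnostics(fit: LMMFit, data: GroupedData) -> DiagnosticsReport:
    """Model-assumption checks: collinearity (VIF), residual normality
    (Shapiro-Wilk), heteroscedasticity (slope of |resid| on fitted) and
    residual autocorrelation after AR(1) whitening."""
    import statsmodels.api as sm

    X = data.X
    names = data.x_names
    vifs = {}
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        coef, res_ss, rank, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        tot = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        resid = X[:, j] - others @ coef
        r2 = 1.0 - float((resid ** 2).sum()) / tot if tot > 0 else 1.0
        vifs[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, dtype=float)

    w = _whitened_residuals(fit, data)
    sample = w if w.size <= 4500 else w[:: int(np.ceil(w.size / 4500))]
    sw = stats.shapiro(sample)

    fitted = data.X @ fit.beta.to_numpy()
    ols = sm.OLS(np.abs(w), sm.add_constant(fitted)).fit()
    hetero_slope = float(ols.params[1])
    hetero_p = float(ols.pvalues[1])

    inner = np.ones(data.n_obs, dtype=bool)
    inner[data.starts] = False
    a, b = w[inner], np.roll(w, 1)[inner]
    lag1 = float(np.corrcoef(a, b)[0, 1]) if a.size > 2 else np.nan

    return DiagnosticsReport(
        vif=vif, shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
        normality_flag=sw.pvalue < 0.01,
        hetero_slope=hetero_slope, hetero_p=hetero_p,
        hetero_flag=hetero_p < 0.01,
        lag1_autocorr=lag1,
    )
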