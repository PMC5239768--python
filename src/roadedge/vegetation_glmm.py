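"""Negative-binomial mixed models for community metrics vs vegetation.

Community metrics (counts) are regressed on standardized vegetation
predictors with a plot-level random intercept:

    y_ij ~ NB2(mu_ij, theta),   log mu_ij = x_ij' beta + u_j,
    u_j ~ Normal(0, sigma^2)

The marginal likelihood is maximised under a Laplace approximation (exact
1-D mode finding per plot, vectorised Newton), which is accurate for a
single intercept-only grouping factor.  Residual spatial autocorrelation is
checked with a Monte-Carlo permutation test of Moran's I on inverse-distance
row-standardised weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._nb import nb_logpmf

__all__ = [
    "standardize",
    "GlmmFit",
    "fit_nb_glmm",
    "NegativeBinomialGLMM",
    "MoranResult",
    "morans_i",
    "morans_i_test",
]


def standardize(x, name: str = "variable"):
    """Centre and scale to unit sample SD: (x - mean) / SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot standardize constant vector: {name}")
    return (x - x.mean()) / sd


@dataclass
class GlmmFit:
    names: list
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma_plot: float
    theta: float
    llf: float
    converged: bool
    boundary_sigma: bool  # random-effect SD on the zero boundary

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p},
            index=self.names,
        )


_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -6.0, 3.0
_LOG_THETA_MIN, _LOG_THETA_MAX = -4.0, 8.0


class _LaplaceNB:
    """Laplace-approximate marginal log-likelihood machinery."""

    def __init__(self, X, y, group_idx, n_groups):
        self.X = X
        self.y = y
        self.gi = group_idx
        self.J = n_groups

    def _modes(self, eta, theta, sigma2):
        """Per-group posterior modes of u by vectorised Newton."""
        u = np.zeros(self.J)
        y, gi = self.y, self.gi
        for _ in range(50):
            mu = np.exp(eta + u[gi])
            score = np.bincount(
                gi, weights=(y - mu) * theta / (theta + mu), minlength=self.J
            ) - u / sigma2
            info = np.bincount(
                gi,
                weights=mu * theta * (theta + y) / (theta + mu) ** 2,
                minlength=self.J,
            ) + 1.0 / sigma2
            step = score / info
            # dampen large steps for stability
            step = np.clip(step, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return u

    def loglik(self, params):
        p = self.X.shape[1]
        beta = params[:p]
        theta = np.exp(np.clip(params[p], _LOG_THETA_MIN, _LOG_THETA_MAX))
        log_sigma = np.clip(params[p + 1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        sigma2 = np.exp(2.0 * log_sigma)
        eta = self.X @ beta
        u = self._modes(eta, theta, sigma2)
        mu = np.exp(eta + u[self.gi])
        ll_data = np.bincount(
            self.gi, weights=nb_logpmf(self.y, mu, theta), minlength=self.J
        )
        h = ll_data - 0.5 * u**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        neg_h2 = np.bincount(
            self.gi,
            weights=mu * theta * (theta + self.y) / (theta + mu) ** 2,
            minlength=self.J,
        ) + 1.0 / sigma2
        return float(np.sum(h + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(neg_h2)))


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    h = eps * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            H[i, j] = H[j, i] = fij / (4 * h[i] * h[j])
    return H


def fit_nb_glmm(response, predictors: pd.DataFrame, plot_ids) -> GlmmFit:
    """NB GLMM with a plot random intercept (Laplace approximation).

    ``predictors`` should already be standardized (see :func:`standardize`);
    an intercept is added internally.  A fit whose random-intercept SD
    collapses to the boundary is returned as a valid fit with
    ``boundary_sigma`` set (it then coincides with the plain NB GLM).
    """
    y = np.asarray(response, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(predictors, dtype=float)])
    names = ["intercept"] + list(predictors.columns)
    codes, uniques = pd.factorize(np.asarray(plot_ids))
    if len(uniques) < 2:
        raise ValueError("need >= 2 plots for a random intercept")
    lap = _LaplaceNB(X, y, codes, len(uniques))

    import statsmodels.api as sm

    with np.errstate(all="ignore"):
        start_beta = sm.Poisson(y, X).fit(disp=0, maxiter=100).params
    x0 = np.concatenate([start_beta, [0.0], [np.log(0.3)]])

    obj = lambda p: -lap.loglik(p)
    res = minimize(
        obj, x0, method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1]
        + [(_LOG_THETA_MIN, _LOG_THETA_MAX), (_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)],
        options={"maxiter": 500, "ftol": 1e-11},
    )
    p = X.shape[1]
    beta = res.x[:p]
    theta = float(np.exp(res.x[p]))
    log_sigma = res.x[p + 1]
    sigma = float(np.exp(log_sigma))
    boundary = bool(log_sigma <= _LOG_SIGMA_MIN + 1e-6)

    H = _numerical_hessian(obj, res.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pv = 2 * norm.sf(np.abs(z))
    return GlmmFit(
        names, beta, se, z, pv,
        0.0 if boundary else sigma, theta, -float(res.fun),
        bool(res.success), boundary,
    )


class NegativeBinomialGLMM(BaseEstimator):
    """sklearn-style wrapper: ``fit(X, y, groups=plot_ids)``."""

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (plot ids) are required")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        res = fit_nb_glmm(y, X, groups)
        self.result_ = res
        self.coef_ = res.coef[1:]
        self.intercept_ = res.coef[0]
        self.theta_ = res.theta
        self.sigma_plot_ = res.sigma_plot
        self.llf_ = res.llf
        return self


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_perm: int


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(coords))
    n = len(coords)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident coordinates: inverse-distance weight undefined")
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    W /= W.sum(axis=1, keepdims=True)  # row-standardize
    return W


def _knn_weights(coords: np.ndarray, k: int) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    n = len(coords)
    W = np.zeros((n, n))
    idx = np.argsort(d, axis=1)[:, :k]
    for i in range(n):
        W[i, idx[i]] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def morans_i(values, W: np.ndarray) -> float:
    """Moran's I = (n/W_tot) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    n = len(x)
    w_tot = W.sum()
    return float((n / w_tot) * (z @ W @ z) / (z @ z))


def morans_i_test(
    residuals,
    coordinates,
    n_perm: int = 1000,
    seed: int | None = None,
    weights: str = "inverse_distance",
    k: int = 8,
) -> MoranResult:
    """Monte-Carlo permutation test for residual spatial autocorrelation.

    Residuals are permuted over the fixed coordinate set; the two-sided
    p-value compares |I - E[I]| with its permutation distribution, where
    E[I] = -1/(n-1) under no autocorrelation.
    """
    x = np.asarray(residuals, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 points")
    if weights == "inverse_distance":
        W = _inverse_distance_weights(coords)
    elif weights == "knn":
        W = _knn_weights(coords, k)
    else:
        raise ValueError("weights must be 'inverse_distance' or 'knn'")
    e_i = -1.0 / (len(x) - 1)
    i_obs = morans_i(x, W)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        i_p = morans_i(rng.permutation(x), W)
        if abs(i_p - e_i) >= abs(i_obs - e_i) - 1e-15:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MoranResult(i_obs, e_i, float(p), n_perm)
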