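"""Distance-gradient regressions: single-slope and piecewise (breakpoint) fits.

Community responses (abundance, biomass, richness, per-group abundance) are
modelled against distance from the road edge with a negative-binomial GLM
(log link, NB2), or an ordinary linear model for Gaussian vegetation
variables.  A two-segment model with basis {d, (d - psi)+} captures an
abrupt change of gradient at a breakpoint psi, which is estimated by a
profile-likelihood grid search; the single-slope and piecewise fits are then
compared by AIC, with the piecewise model charged two extra parameters (the
slope change and the breakpoint itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._nb import nb_rvs

__all__ = [
    "GlmFit",
    "PiecewiseFit",
    "fit_nb_glm",
    "fit_piecewise",
    "select_model",
    "NegativeBinomialGradient",
    "PiecewiseGradient",
]


@dataclass
class GlmFit:
    """Single-slope count (or Gaussian) regression against distance."""

    beta0: float
    beta1: float
    theta: float  # NB size; inf = Poisson limit / Gaussian
    llf: float
    aic: float
    k_params: int
    t_distance: float
    p_distance: float
    se: np.ndarray
    converged: bool
    family: str = "nb"

    def predict(self, distance) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(distance, dtype=float)
        return eta if self.family == "gaussian" else np.exp(eta)


@dataclass
class PiecewiseFit:
    """Two-segment fit: slope beta1 before psi, slope change beta2 at psi."""

    beta0: float
    beta1: float
    beta2: float
    psi: float
    psi_se: float
    theta: float
    llf: float
    aic_piecewise: float
    aic_linear: float
    t_distance: float
    p_distance: float
    no_breakpoint: bool
    converged: bool
    family: str = "nb"
    linear_fit: GlmFit | None = None
    profile: dict = field(default_factory=dict, repr=False)

    @property
    def delta_aic(self) -> float:
        return self.aic_linear - self.aic_piecewise

    def predict(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        eta = self.beta0 + self.beta1 * d + self.beta2 * np.maximum(d - self.psi, 0.0)
        return eta if self.family == "gaussian" else np.exp(eta)


def _gaussian_profile_llf(X: np.ndarray, y: np.ndarray):
    """OLS coefficients and a profile 'log-likelihood' −(n/2)·log(SSR/n).

    Monotone in −SSR, so it ranks breakpoint candidates identically to the
    exact Gaussian likelihood while remaining finite for noiseless data.
    """
    beta, ssr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    n = len(y)
    llf = -0.5 * n * np.log(max(ssr, 1e-300) / n)
    return beta, ssr, llf


def _fit_count_glm(X: np.ndarray, y: np.ndarray, start_params=None):
    """NB2 GLM by joint MLE (statsmodels); Poisson fallback on the boundary.

    Returns (params, bse, tvalues, pvalues, llf, theta, converged).
    Underdispersed or degenerate data push the NB dispersion MLE to the
    alpha -> 0 boundary where the NB fit is ill-conditioned; a Poisson GLM
    (theta = inf) is the correct limiting model there.
    """
    y = np.asarray(y, dtype=float)
    nb_res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, X)
            sp = start_params
            if sp is None:
                po = sm.Poisson(y, X).fit(disp=0)
                sp = np.append(po.params, 0.5)
            nb_res = model.fit(start_params=sp, method="bfgs", maxiter=200, disp=0)
            if not nb_res.mle_retvals.get("converged", False):
                nb_res = model.fit(
                    start_params=nb_res.params, method="nm", maxiter=2000, disp=0
                )
        except Exception:
            nb_res = None

    if nb_res is not None and np.all(np.isfinite(nb_res.params)):
        alpha = float(nb_res.params[-1])
        if alpha > 1e-4 and np.isfinite(nb_res.llf):
            k = X.shape[1]
            bse = np.asarray(nb_res.bse)[:k]
            tv = np.asarray(nb_res.tvalues)[:k]
            pv = np.asarray(nb_res.pvalues)[:k]
            conv = bool(nb_res.mle_retvals.get("converged", True))
            return (
                np.asarray(nb_res.params)[:k],
                bse,
                tv,
                pv,
                float(nb_res.llf),
                1.0 / alpha,
                conv,
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        po = sm.Poisson(y, X).fit(disp=0)
    return (
        np.asarray(po.params),
        np.asarray(po.bse),
        np.asarray(po.tvalues),
        np.asarray(po.pvalues),
        float(po.llf),
        np.inf,
        bool(po.mle_retvals.get("converged", True)),
    )


def fit_nb_glm(response, distance, gaussian: bool = False) -> GlmFit:
    """Single-slope regression of a per-trap response on distance (m).

    Counts get an NB GLM with log link and jointly estimated dispersion;
    ``gaussian=True`` fits an ordinary linear model instead.  AIC counts the
    dispersion/variance parameter.  Non-convergence is flagged on the
    result, never returned as silent NaN.
    """
    y = np.asarray(response, dtype=float)
    d = np.asarray(distance, dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct distances")
    if not gaussian and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("counts must be non-negative integers")
    X = np.column_stack([np.ones_like(d), d])
    if gaussian:
        res = sm.OLS(y, X).fit()
        k = 3  # beta0, beta1, sigma
        return GlmFit(
            float(res.params[0]),
            float(res.params[1]),
            np.inf,
            float(res.llf),
            -2.0 * float(res.llf) + 2 * k,
            k,
            float(res.tvalues[1]),
            float(res.pvalues[1]),
            np.asarray(res.bse),
            True,
            "gaussian",
        )
    params, bse, tv, pv, llf, theta, conv = _fit_count_glm(X, y)
    k = 3 if np.isfinite(theta) else 2
    return GlmFit(
        float(params[0]),
        float(params[1]),
        theta,
        llf,
        -2.0 * llf + 2 * k,
        k,
        float(tv[1]),
        float(pv[1]),
        bse,
        conv,
        "nb",
    )


def _piecewise_design(d: np.ndarray, psi: float) -> np.ndarray:
    return np.column_stack([np.ones_like(d), d, np.maximum(d - psi, 0.0)])


def _psi_grid(d: np.ndarray, grid_step: float) -> np.ndarray:
    u = np.unique(d)
    if len(u) < 4:
        raise ValueError("need >= 4 distinct distances for a breakpoint search")
    lo, hi = u[1], u[-2]
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    return grid[(grid >= lo) & (grid <= hi)]


def _profile_search(d, y, grid, gaussian):
    """Profile log-likelihood over breakpoint candidates; warm-started."""
    llfs = np.empty(len(grid))
    fits = []
    start = None
    for j, psi in enumerate(grid):
        X = _piecewise_design(d, psi)
        if gaussian:
            beta, ssr, llf = _gaussian_profile_llf(X, y)
            fits.append((beta, ssr))
            llfs[j] = llf
        else:
            params, bse, tv, pv, llf, theta, conv = _fit_count_glm(X, y, start)
            start = (
                np.append(params, 1.0 / theta) if np.isfinite(theta) else None
            )
            fits.append((params, bse, tv, pv, theta, conv))
            llfs[j] = llf
    return llfs, fits


def fit_piecewise(
    response,
    distance,
    gaussian: bool = False,
    grid_step: float = 1.0,
    se_boot: int = 200,
    seed: int | None = None,
) -> PiecewiseFit:
    """Two-segment (breakpoint) regression against distance.

    The breakpoint psi is estimated by maximising the profile likelihood
    over a candidate grid (default 1 m resolution between the 2nd and
    penultimate distinct distances); the standard error of psi comes from a
    seeded parametric bootstrap (``se_boot`` resamples; 0 skips it).  If the
    profile has no improvement over the single-slope model the linear fit is
    returned with ``no_breakpoint`` set.
    """
    y = np.asarray(response, dtype=float)
    d = np.asarray(distance, dtype=float)
    lin = fit_nb_glm(y, d, gaussian=gaussian)
    grid = _psi_grid(d, grid_step)
    llfs, fits = _profile_search(d, y, grid, gaussian)
    j = int(np.argmax(llfs))
    psi_hat = float(grid[j])

    if llfs[j] <= lin.llf + 1e-9:
        return PiecewiseFit(
            lin.beta0, lin.beta1, 0.0, psi_hat, np.nan, lin.theta, lin.llf,
            lin.aic, lin.aic, lin.t_distance, lin.p_distance,
            no_breakpoint=True, converged=lin.converged,
            family=lin.family, linear_fit=lin,
            profile={"grid": grid, "llf": llfs},
        )

    k_pw = 5  # beta0, beta1, beta2, dispersion/sigma, psi
    if gaussian:
        beta, ssr = fits[j]
        n = len(y)
        sigma2 = max(ssr, 1e-300) / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        X = _piecewise_design(d, psi_hat)
        XtX_inv = np.linalg.pinv(X.T @ X)
        dof = max(n - X.shape[1], 1)
        bse = np.sqrt(np.diag(XtX_inv) * ssr / dof)
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = beta / np.where(bse > 0, bse, np.nan)
        from scipy.stats import t as tdist

        pv = 2 * tdist.sf(np.abs(tv), dof)
        theta, conv = np.inf, True
        params = beta
    else:
        params, bse, tv, pv, theta, conv = fits[j]
        llf = float(llfs[j])
        if not np.isfinite(theta):
            k_pw = 4

    aic_pw = -2.0 * llf + 2 * k_pw

    psi_se = np.nan
    if se_boot > 0:
        rng = np.random.default_rng(seed)
        mu = (
            params[0] + params[1] * d + params[2] * np.maximum(d - psi_hat, 0.0)
        )
        psis = []
        for _ in range(se_boot):
            if gaussian:
                sigma = np.sqrt(max(ssr, 0.0) / len(y))
                yb = mu + rng.normal(0.0, sigma, size=len(y))
            else:
                yb = nb_rvs(rng, np.exp(mu), theta)
            try:
                llb, _ = _profile_search(d, yb, grid, gaussian)
                psis.append(grid[int(np.argmax(llb))])
            except Exception:
                continue
        if len(psis) > 1:
            psi_se = float(np.std(psis, ddof=1))

    return PiecewiseFit(
        float(params[0]), float(params[1]), float(params[2]),
        psi_hat, psi_se, theta, llf, aic_pw, lin.aic,
        float(tv[1]), float(pv[1]),
        no_breakpoint=False, converged=conv, family=lin.family,
        linear_fit=lin, profile={"grid": grid, "llf": llfs},
    )


def select_model(fit_linear: GlmFit, fit_piecewise: PiecewiseFit):
    """AIC model choice between single-slope and breakpoint fits.

    Returns ``(label, delta_aic)`` with ``delta_aic = aic_linear -
    aic_piecewise``; ties go to the simpler single-slope model.
    """
    delta = fit_linear.aic - fit_piecewise.aic_piecewise
    label = "piecewise" if delta > 0 else "linear"
    return label, float(delta)


def _as_1d_distance(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("distance design must have a single column")
        X = X[:, 0]
    return X


class NegativeBinomialGradient(BaseEstimator):
    """sklearn-style single-slope NB (or Gaussian) gradient regression.

    Parameters
    ----------
    gaussian : fit an ordinary linear model instead of the NB GLM.
    """

    def __init__(self, gaussian: bool = False):
        self.gaussian = gaussian

    def fit(self, X, y):
        d = _as_1d_distance(X)
        res = fit_nb_glm(y, d, gaussian=self.gaussian)
        self.result_ = res
        self.coef_ = np.array([res.beta1])
        self.intercept_ = res.beta0
        self.theta_ = res.theta
        self.aic_ = res.aic
        self.llf_ = res.llf
        return self

    def predict(self, X):
        return self.result_.predict(_as_1d_distance(X))


class PiecewiseGradient(BaseEstimator):
    """sklearn-style two-segment gradient regression with breakpoint search."""

    def __init__(
        self,
        gaussian: bool = False,
        grid_step: float = 1.0,
        se_boot: int = 200,
        seed: int | None = None,
    ):
        self.gaussian = gaussian
        self.grid_step = grid_step
        self.se_boot = se_boot
        self.seed = seed

    def fit(self, X, y):
        d = _as_1d_distance(X)
        res = fit_piecewise(
            y, d, gaussian=self.gaussian, grid_step=self.grid_step,
            se_boot=self.se_boot, seed=self.seed,
        )
        self.result_ = res
        self.psi_ = res.psi
        self.psi_se_ = res.psi_se
        self.coef_ = np.array([res.beta1, res.beta2])
        self.intercept_ = res.beta0
        self.theta_ = res.theta
        self.aic_ = res.aic_piecewise
        self.selected_, self.delta_aic_ = select_model(res.linear_fit, res)
        return self

    def predict(self, X):
        return self.result_.predict(_as_1d_distance(X))
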