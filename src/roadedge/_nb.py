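"""Shared negative-binomial (NB2) likelihood utilities.

Parameterisation used throughout: mean ``mu`` and size/dispersion ``theta``
with ``Var[Y] = mu + mu**2 / theta`` (theta -> inf is the Poisson limit).
statsmodels' ``alpha`` is ``1 / theta``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def nb_logpmf(y, mu, theta):
    """Element-wise NB2 log pmf; broadcasts. theta=inf gives Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.ndim(theta) == 0 and np.isinf(theta):
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    theta = np.asarray(theta, dtype=float)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def nb_loglik(y, mu, theta, axis=None):
    """Summed NB2 log likelihood (with 0*log(0) := 0 for mu=0 guarded)."""
    mu = np.clip(mu, 1e-12, None)
    return np.sum(nb_logpmf(y, mu, theta), axis=axis)


def profile_theta_mle(y, mu, log_theta_grid=None, refine=True):
    """MLE of theta given fixed means, by grid + golden-section refinement.

    Cheap 1-D profile used where many fits are needed (e.g. the multivariate
    composition bootstrap). For a single careful fit use statsmodels instead.
    """
    y = np.asarray(y, dtype=float)
    if log_theta_grid is None:
        log_theta_grid = np.linspace(-4.0, 8.0, 49)
    ll = np.array([nb_loglik(y, mu, np.exp(lt)) for lt in log_theta_grid])
    i = int(np.argmax(ll))
    if not refine:
        return float(np.exp(log_theta_grid[i]))
    lo = log_theta_grid[max(i - 1, 0)]
    hi = log_theta_grid[min(i + 1, len(log_theta_grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lt: -nb_loglik(y, mu, np.exp(lt)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def nb_rvs(rng, mu, theta, size=None):
    """Draw NB2 variates via the Gamma-Poisson mixture (handles theta=inf)."""
    mu = np.asarray(mu, dtype=float)
    if np.isinf(theta):
        return rng.poisson(mu, size=size)
    lam = rng.gamma(shape=theta, scale=mu / theta, size=size)
    return rng.poisson(lam)
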