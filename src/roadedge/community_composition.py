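"""Compositional change with distance from the edge.

Assemblages are standardised to proportions of total individuals per row
(distance class or trap), compared with Bray-Curtis dissimilarity, ordinated
by non-metric multidimensional scaling (NMDS, Kruskal stress-1), and the
edge (<= 100 m) versus interior (>= 170 m) contrast is tested with a
model-based multivariate procedure: per-species negative-binomial GLMs whose
likelihood-ratio statistics are summed over species, with the null
distribution generated by trap-level resampling of randomized
probability-integral-transform residuals under the null fit (this preserves
the between-species correlation within traps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from ._nb import nb_logpmf

__all__ = [
    "standardize_proportions",
    "bray_curtis",
    "NMDS",
    "nmds",
    "multivariate_edge_test",
    "composition_matrix",
    "MultivariateTestResult",
]

EDGE_MAX_M = 100.0
INTERIOR_MIN_M = 170.0


def composition_matrix(
    samples: pd.DataFrame, by: str = "distance_class"
) -> tuple[pd.DataFrame, pd.Series]:
    """Species-by-row count matrix from long-format trap samples.

    ``by='distance_class'`` pools road-edge traps per distance and all
    interior traps into one row; ``by='trap'`` keeps one row per trap
    (road-edge and interior only).  Returns ``(matrix, is_edge flags)`` with
    edge = within 100 m of the road, interior = >= 170 m.
    """
    s = samples[samples["habitat"].isin(["road_edge", "interior"])].copy()
    if by == "distance_class":
        s["row"] = np.where(
            s["habitat"] == "road_edge",
            s["distance_m"].map(lambda d: f"edge_{d:g}m"),
            "interior",
        )
    elif by == "trap":
        s["row"] = s["trap_id"]
    else:
        raise ValueError("by must be 'distance_class' or 'trap'")
    mat = s.pivot_table(index="row", columns="species", values="count",
                        aggfunc="sum", fill_value=0)
    flag = (
        s.drop_duplicates("row").set_index("row")["habitat"] == "road_edge"
    ).reindex(mat.index)
    return mat, flag


def standardize_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise counts to proportions of the row total.

    Rows with zero total are dropped with a warning.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero row(s): "
            f"{list(counts.index[zero])}"
        )
        counts = counts.loc[~zero]
        totals = totals[~zero]
    return counts.div(totals, axis=0)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) between two rows."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("entries must be non-negative")
    if a.sum() + b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero rows")
    return float(_scipy_braycurtis(a, b))


def bray_curtis_matrix(rows: pd.DataFrame) -> np.ndarray:
    n = len(rows)
    X = rows.to_numpy(dtype=float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return D


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling on a precomputed dissimilarity.

    Thin estimator over sklearn's SMACOF implementation with monotone
    regression; the best of ``n_restarts`` seeded starts is kept and
    Kruskal stress-1 is exposed as ``stress_``.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 8,
                 max_iter: int = 500, seed: int | None = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.seed = seed

    def fit_transform(self, D):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        mds = MDS(
            n_components=self.n_components,
            metric=False,
            n_init=self.n_restarts,
            max_iter=self.max_iter,
            eps=1e-9,
            dissimilarity="precomputed",
            normalized_stress=True,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self.embedding_ = mds.fit_transform(D)
        self.stress_ = float(mds.stress_)
        return self.embedding_

    def fit(self, D, y=None):
        self.fit_transform(D)
        return self


def nmds(D, k: int = 2, n_restarts: int = 8, seed: int | None = 0):
    """Functional wrapper: returns (coordinates, stress-1)."""
    est = NMDS(n_components=k, n_restarts=n_restarts, seed=seed)
    coords = est.fit_transform(D)
    return coords, est.stress_


# ---------------------------------------------------------------------------
# multivariate edge-vs-interior test


@dataclass
class MultivariateTestResult:
    statistic: float  # sum over species of per-species LR statistics
    p_value: float
    n_boot: int
    n_species: int
    per_species_lr: pd.Series


def _theta_profile_grid(Y, Mu, log_theta_grid):
    """Per-species profile over theta: returns (best log-lik, theta) arrays.

    Y, Mu are (n_traps, n_species); vectorised over species and grid.
    """
    thetas = np.exp(log_theta_grid)
    Mu = np.clip(Mu, 1e-10, None)
    # broadcast over the grid in one pass: (grid, traps, species)
    ll = nb_logpmf(Y[None], Mu[None], thetas[:, None, None]).sum(axis=1)
    best = np.argmax(ll, axis=0)
    return ll[best, np.arange(Y.shape[1])], thetas[best]


_LOG_THETA_GRID = np.linspace(-4.0, 8.0, 61)


def _sum_lr_statistic(Y, is_edge, log_theta_grid=_LOG_THETA_GRID):
    """Sum over species of NB likelihood-ratio stats for the group factor.

    Group-mean MLEs are the sample means under the log link, so only the
    dispersion needs a 1-D profile per species.
    """
    mu0 = Y.mean(axis=0, keepdims=True)
    mu_e = Y[is_edge].mean(axis=0, keepdims=True)
    mu_i = Y[~is_edge].mean(axis=0, keepdims=True)
    Mu1 = np.where(is_edge[:, None], mu_e, mu_i)
    ll0, th0 = _theta_profile_grid(Y, np.broadcast_to(mu0, Y.shape), log_theta_grid)
    ll1, _ = _theta_profile_grid(Y, Mu1, log_theta_grid)
    lr = np.clip(2.0 * (ll1 - ll0), 0.0, None)
    return lr, mu0.ravel(), th0


def _null_quantile_tables(mu0, th0, tail=1e-9):
    """Per-species NB CDF tables for PIT residuals and their inversion."""
    tables = []
    from scipy.stats import nbinom

    for m, th in zip(mu0, th0):
        p = th / (th + max(m, 1e-10))
        ymax = int(nbinom.ppf(1.0 - tail, th, p)) + 1
        cdf = nbinom.cdf(np.arange(ymax + 1), th, p)
        tables.append(cdf)
    return tables


def multivariate_edge_test(
    counts: pd.DataFrame,
    is_edge,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MultivariateTestResult:
    """Model-based multivariate test of the edge vs interior contrast.

    Per-species NB GLMs with the edge/interior factor give likelihood-ratio
    statistics whose sum is the test statistic; the null distribution comes
    from ``n_boot`` trap-level resamples of randomized PIT residuals under
    the null (no-contrast) fit, with the usual +1 permutation correction on
    the p-value.  All-zero species are dropped with a warning.
    """
    is_edge = np.asarray(is_edge, dtype=bool)
    if is_edge.sum() < 2 or (~is_edge).sum() < 2:
        raise ValueError("need >= 2 rows per group")
    Y = counts.to_numpy(dtype=float)
    keep = Y.sum(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero species")
        Y = Y[:, keep]
    names = counts.columns[keep]

    # one grid for observed and bootstrap statistics keeps them exchangeable
    grid = np.linspace(-4.0, 8.0, 25)
    lr, mu0, th0 = _sum_lr_statistic(Y, is_edge, grid)
    stat_obs = float(lr.sum())

    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    # randomized PIT residuals under the null fit
    tables = _null_quantile_tables(mu0, th0)
    U = np.empty_like(Y)
    V = rng.random(Y.shape)
    for s, cdf in enumerate(tables):
        y = Y[:, s].astype(int)
        y = np.clip(y, 0, len(cdf) - 1)
        lo = np.where(y > 0, cdf[np.maximum(y - 1, 0)], 0.0)
        hi = cdf[y]
        U[:, s] = lo + V[:, s] * (hi - lo)

    count_ge = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Ub = U[idx]
        Yb = np.empty_like(Ub)
        for s, cdf in enumerate(tables):
            Yb[:, s] = np.searchsorted(cdf, Ub[:, s], side="left")
        lr_b, _, _ = _sum_lr_statistic(Yb, is_edge, grid)
        if lr_b.sum() >= stat_obs - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (n_boot + 1.0)
    return MultivariateTestResult(
        stat_obs, float(p), n_boot, Y.shape[1], pd.Series(lr, index=names)
    )
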