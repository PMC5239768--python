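"""Standardisation, NB mixed model, Moran's-I permutation test."""

import subprocess
import sys
import tempfile
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from roadedge._nb import nb_rvs
from roadedge.vegetation_glmm import (
    NegativeBinomialGLMM,
    fit_nb_glmm,
    morans_i,
    morans_i_test,
    standardize,
    _inverse_distance_weights,
)


class TestStandardize:
    def test_hand_arithmetic(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_zero_mean_unit_sd(self, rng):
        z = standardize(rng.normal(3.0, 5.0, 100))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=30)
        assert np.allclose(standardize(standardize(x)), standardize(x))

    def test_constant_vector_named_in_error(self):
        with pytest.raises(ValueError, match="canopy"):
            standardize([2.0, 2.0, 2.0], name="canopy")


def simulate_glmm(rng, n_plots=24, per_plot=7, beta=None, sigma=0.5,
                  theta=2.0, intercept=2.0, n_pred=8):
    plot = np.repeat(np.arange(n_plots), per_plot)
    X = pd.DataFrame(
        rng.normal(size=(n_plots * per_plot, n_pred)),
        columns=[f"v{i}" for i in range(n_pred)],
    )
    Xs = pd.DataFrame({c: standardize(X[c]) for c in X.columns})
    if beta is None:
        beta = np.zeros(n_pred)
    u = rng.normal(0.0, sigma, n_plots)
    eta = intercept + Xs.to_numpy() @ beta + u[plot]
    y = nb_rvs(rng, np.exp(eta), theta)
    return y, Xs, plot


class TestGlmm:
    def test_zero_plot_sd_matches_plain_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        y, Xs, plot = simulate_glmm(rng, sigma=0.0, beta=np.r_[0.4, np.zeros(7)])
        fit = fit_nb_glmm(y, Xs, plot)
        X = np.column_stack([np.ones(len(y)), Xs.to_numpy()])
        glm = sm.NegativeBinomial(y.astype(float), X).fit(disp=0)
        # mixed fit collapses towards the GLM when there is no plot effect
        assert np.allclose(fit.coef, glm.params[:-1], atol=0.02)
        assert fit.sigma_plot < 0.15

    def test_known_coefficient_recovered_single_fit(self):
        rng = np.random.default_rng(11)
        beta = np.r_[0.4, np.zeros(7)]
        y, Xs, plot = simulate_glmm(rng, beta=beta)
        fit = fit_nb_glmm(y, Xs, plot)
        assert abs(fit.coef[1] - 0.4) <= 2 * fit.se[1]
        assert 0.2 < fit.sigma_plot < 1.0

    def test_extra_noise_predictor_leaves_fit_stable(self):
        rng = np.random.default_rng(21)
        beta = np.r_[0.4, np.zeros(7)]
        y, Xs, plot = simulate_glmm(rng, beta=beta)
        fit8 = fit_nb_glmm(y, Xs, plot)
        X9 = Xs.copy()
        X9["noise"] = standardize(rng.normal(size=len(y)))
        fit9 = fit_nb_glmm(y, X9, plot)
        assert np.all(np.abs(fit9.coef[:9] - fit8.coef) <= fit8.se + 1e-6)

    def test_affine_rescaling_invariance_via_standardisation(self):
        rng = np.random.default_rng(5)
        y, Xs, plot = simulate_glmm(rng, beta=np.r_[0.3, np.zeros(7)])
        fit1 = fit_nb_glmm(y, Xs, plot)
        rescaled = pd.DataFrame(
            {c: standardize(37.0 * Xs[c] + 11.0) for c in Xs.columns}
        )
        fit2 = fit_nb_glmm(y, rescaled, plot)
        assert np.allclose(fit1.coef, fit2.coef, atol=1e-6)

    def test_estimator_api(self):
        rng = np.random.default_rng(9)
        y, Xs, plot = simulate_glmm(rng, n_plots=10, per_plot=5)
        est = NegativeBinomialGLMM().fit(Xs, y, groups=plot)
        assert est.coef_.shape == (8,)
        assert est.theta_ > 0

    def test_requires_two_plots(self):
        with pytest.raises(ValueError):
            fit_nb_glmm([1, 2, 3], pd.DataFrame({"a": [0.1, 0.2, 0.3]}), ["p"] * 3)

    def test_matches_glmmtmb_oracle(self, tmp_path):
        # independent cross-check against R's glmmTMB on one small dataset
        rng = np.random.default_rng(13)
        y, Xs, plot = simulate_glmm(rng, n_plots=20, per_plot=6,
                                    beta=np.r_[0.4, -0.3, np.zeros(6)])
        fit = fit_nb_glmm(y, Xs, plot)
        df = Xs.copy()
        df["y"] = y
        df["plot"] = plot
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmmTMB(y ~ v0+v1+v2+v3+v4+v5+v6+v7 + (1|plot), data=d,\n"
            "             family=nbinom2)\n"
            "cat(fixef(m)$cond, sep=',')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(rscript)],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        r_coef = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.allclose(fit.coef, r_coef, atol=0.02)


def brute_force_moran(x, W):
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / W.sum()) * num / den


class TestMoran:
    def test_matches_brute_force(self, rng):
        coords = rng.uniform(0, 100, (12, 2))
        W = _inverse_distance_weights(coords)
        x = rng.normal(size=12)
        assert morans_i(x, W) == pytest.approx(brute_force_moran(x, W), abs=1e-10)

    def test_permutation_mean_near_expectation(self, rng):
        # E[I] = -1/(n-1) over the permutation distribution (n = 5)
        coords = rng.uniform(0, 10, (5, 2))
        W = _inverse_distance_weights(coords)
        x = rng.normal(size=5)
        vals = [morans_i(np.array(p), W) for p in permutations(x)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-0.25)) < max(3 * se, 1e-10)

    def test_seeded_p_matches_exhaustive_enumeration(self, rng):
        coords = rng.uniform(0, 10, (6, 2))
        W = _inverse_distance_weights(coords)
        x = rng.normal(size=6)
        e_i = -1.0 / 5.0
        obs = morans_i(x, W)
        vals = np.array([morans_i(np.array(p), W) for p in permutations(x)])
        p_exact = np.mean(np.abs(vals - e_i) >= abs(obs - e_i) - 1e-15)
        res = morans_i_test(x, coords, n_perm=4000, seed=0)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_value - p_exact) <= 2 * mc_se + 1e-3

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(55)
        n_rep, rej = 400, 0
        coords = rng.uniform(0, 100, (20, 2))
        for _ in range(n_rep):
            res = morans_i_test(rng.normal(size=20), coords, n_perm=199,
                                seed=int(rng.integers(2**31)))
            rej += res.p_value <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_invariant_to_additive_constant(self, rng):
        coords = rng.uniform(0, 10, (8, 2))
        W = _inverse_distance_weights(coords)
        x = rng.normal(size=8)
        assert morans_i(x, W) == pytest.approx(morans_i(x + 100.0, W), abs=1e-9)

    def test_coincident_coordinates_rejected(self):
        coords = np.array([[0, 0], [0, 0], [1, 1], [2, 2]], dtype=float)
        with pytest.raises(ValueError):
            morans_i_test(np.arange(4.0), coords, n_perm=10, seed=0)

    def test_positive_autocorrelation_detected(self, rng):
        coords = rng.uniform(0, 10, (40, 2))
        x = coords[:, 0] + rng.normal(0, 0.5, 40)  # strong spatial trend
        res = morans_i_test(x, coords, n_perm=499, seed=2)
        assert res.I > res.expected_I
        assert res.p_value < 0.01
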