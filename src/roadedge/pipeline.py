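"""Seeded end-to-end orchestration of the edge-effect analysis.

``run_all`` chains: synthetic data generation (or reading of provided CSVs)
-> per-trap community metrics -> MEI/RTEI/DEI profiles -> piecewise gradient
fits -> composition ordination and multivariate test -> vegetation GLMMs
with Moran's-I residual check -> landscape road-edge accounting.  All stage
seeds derive deterministically from one master seed; no global random state
is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    community_composition as cc,
    edge_influence as ei,
    gradient_models as gm,
    landscape_accounting as la,
    synthetic_data as sd,
    traits_biomass as tb,
    vegetation_glmm as vg,
)
from .io import read_samples, read_traits, read_vegetation, write_samples

log = logging.getLogger("roadedge")


@dataclass
class RunConfig:
    samples_path: str | None = None  # None -> simulate
    traits_path: str | None = None
    vegetation_path: str | None = None
    out_dir: str = "roadedge_out"
    seed: int = 0
    n_rand: int = 10_000  # RTEI randomizations
    n_boot: int = 1000  # composition bootstrap
    n_perm: int = 1000  # Moran permutations
    alpha: float = 0.05
    edge_limit_m: float = 170.0
    road_length_km: float = 2403.0
    w_edge: float = la.DEFAULT_W_EDGE
    grid_step_m: float = 5.0  # breakpoint search resolution
    se_boot: int = 50  # breakpoint-SE bootstrap resamples
    responses: tuple = ("abundance", "biomass_g", "richness")

    def validate(self):
        for name in ("n_rand", "n_boot", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_all(config: RunConfig) -> dict:
    """Execute every analysis stage; returns the report bundle as a dict
    and writes one CSV/text artefact per stage into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 8)
    bundle: dict = {"config": config}

    def _stage(name):
        log.info("stage %s", name)

    try:
        _stage("data")
        if config.samples_path is None:
            design = sd.StudyDesign()
            locs = sd.generate_design(design, seed=seeds[0])
            model = sd.CommunityModel(seed=seeds[1])
            samples = sd.generate_counts(locs, model)
            traits = sd.generate_traits(model, seed=seeds[2])
            vegetation = sd.generate_vegetation(locs, seed=seeds[3])
            write_samples(samples, out / "samples.csv")
            traits.to_csv(out / "traits.csv", index=False)
            vegetation.to_csv(out / "vegetation.csv", index=False)
        else:
            samples = read_samples(config.samples_path)
            traits = read_traits(config.traits_path)
            vegetation = (
                read_vegetation(config.vegetation_path)
                if config.vegetation_path
                else None
            )
    except Exception as e:
        raise RuntimeError(f"stage 'data' failed: {e}") from e

    try:
        _stage("metrics")
        traits_full, r2 = tb.extrapolate_mass(traits)
        metrics = tb.trap_metrics(samples, traits_full)
        metrics.to_csv(out / "trap_metrics.csv", index=False)
        bundle["trap_metrics"] = metrics
        bundle["mass_allometry_r2"] = r2
    except Exception as e:
        raise RuntimeError(f"stage 'metrics' failed: {e}") from e

    try:
        _stage("edge_influence")
        ei_rows = []
        dei_rows = []
        rng = np.random.default_rng(seeds[4])
        for var in config.responses:
            results, dei_range = ei.edge_influence_profile(
                metrics, var, n_rand=config.n_rand, alpha=config.alpha,
                seed=int(rng.integers(2**31)),
            )
            for r in results:
                ei_rows.append(
                    dict(variable=var, distance_m=r.distance_m, mei=r.mei,
                         p_value=r.p_value, significant=r.significant)
                )
            dei_rows.append(
                dict(variable=var,
                     dei_m=np.nan if dei_range is None else dei_range[1])
            )
        pd.DataFrame(ei_rows).to_csv(out / "edge_influence.csv", index=False)
        pd.DataFrame(dei_rows).to_csv(out / "dei.csv", index=False)
        bundle["edge_influence"] = pd.DataFrame(ei_rows)
        bundle["dei"] = pd.DataFrame(dei_rows)
    except Exception as e:
        raise RuntimeError(f"stage 'edge_influence' failed: {e}") from e

    try:
        _stage("gradients")
        grad_rows = []
        sub = metrics[metrics["habitat"].isin(["road_edge", "interior"])]
        for var in config.responses:
            y = sub[var].round().astype(int).to_numpy()
            d = sub["distance_m"].to_numpy()
            fit = gm.fit_piecewise(
                y, d, grid_step=config.grid_step_m,
                se_boot=config.se_boot, seed=seeds[5],
            )
            label, delta = gm.select_model(fit.linear_fit, fit)
            grad_rows.append(
                dict(variable=var, model=label, psi_m=fit.psi,
                     psi_se_m=fit.psi_se, beta1=fit.beta1, beta2=fit.beta2,
                     theta=fit.theta, delta_aic=delta,
                     t_distance=fit.t_distance, p_distance=fit.p_distance)
            )
        pd.DataFrame(grad_rows).to_csv(out / "gradient_fits.csv", index=False)
        bundle["gradients"] = pd.DataFrame(grad_rows)
    except Exception as e:
        raise RuntimeError(f"stage 'gradients' failed: {e}") from e

    try:
        _stage("composition")
        mat, flags = cc.composition_matrix(samples, by="distance_class")
        props = cc.standardize_proportions(mat)
        D = cc.bray_curtis_matrix(props)
        coords, stress = cc.nmds(D, seed=seeds[6])
        ord_df = pd.DataFrame(coords, columns=["axis1", "axis2"],
                              index=props.index)
        ord_df["group"] = np.where(flags.loc[props.index], "edge", "interior")
        ord_df.to_csv(out / "ordination.csv")
        tmat, tflags = cc.composition_matrix(samples, by="trap")
        test = cc.multivariate_edge_test(
            tmat, tflags.to_numpy(), n_boot=config.n_boot, seed=seeds[6]
        )
        bundle["ordination"] = ord_df
        bundle["nmds_stress"] = stress
        bundle["composition_test"] = test
        (out / "composition_test.txt").write_text(
            f"sum-LR statistic = {test.statistic:.3f}\n"
            f"p = {test.p_value:.4f} ({test.n_boot} bootstrap resamples, "
            f"{test.n_species} species)\nNMDS stress-1 = {stress:.4f}\n"
        )
    except Exception as e:
        raise RuntimeError(f"stage 'composition' failed: {e}") from e

    try:
        _stage("glmm")
        if vegetation is None and config.samples_path is not None:
            bundle["glmm"] = None
        else:
            veg_cols = [c for c in vegetation.columns if c != "trap_id"]
            merged = metrics.merge(vegetation, on="trap_id")
            merged = merged[merged["habitat"].isin(["road_edge", "interior"])]
            Xs = pd.DataFrame(
                {c: vg.standardize(merged[c], c) for c in veg_cols}
            )
            glmm_rows = []
            moran_rows = []
            for var in ("abundance", "biomass_g"):
                y = merged[var].round().astype(int).to_numpy()
                fit = vg.fit_nb_glmm(y, Xs, merged["plot_id"])
                s = fit.summary()
                s.insert(0, "response", var)
                glmm_rows.append(s)
                # residuals aggregated to plot mid-points for the spatial test
                mu = np.exp(
                    fit.coef[0] + Xs.to_numpy() @ fit.coef[1:]
                )
                resid = (y - mu) / np.sqrt(mu + mu**2 / fit.theta)
                pr = pd.DataFrame(
                    {"plot_id": merged["plot_id"], "resid": resid,
                     "x": merged["x"], "y": merged["y"]}
                ).groupby("plot_id").mean()
                mres = vg.morans_i_test(
                    pr["resid"].to_numpy(), pr[["x", "y"]].to_numpy(),
                    n_perm=config.n_perm, seed=seeds[7],
                )
                moran_rows.append(
                    dict(response=var, moran_I=mres.I,
                         expected_I=mres.expected_I, p_value=mres.p_value)
                )
            glmm_df = pd.concat(glmm_rows)
            glmm_df.to_csv(out / "glmm_coefficients.csv")
            pd.DataFrame(moran_rows).to_csv(out / "moran.csv", index=False)
            bundle["glmm"] = glmm_df
            bundle["moran"] = pd.DataFrame(moran_rows)
    except Exception as e:
        raise RuntimeError(f"stage 'glmm' failed: {e}") from e

    try:
        _stage("landscape")
        hab_means = (
            metrics.groupby("habitat")[list(config.responses)].mean().T
        )
        mm = pd.DataFrame(
            {"interior": hab_means["interior"],
             "edge": hab_means["road_edge"]}
        )
        if "primary" in hab_means.columns:
            mm["primary"] = hab_means["primary"]
        summary = la.landscape_summary(
            mm, road_length_km=config.road_length_km,
            edge_limit_km=config.edge_limit_m / 1000.0,
            w_edge=config.w_edge,
        )
        summary.metrics.to_csv(out / "landscape.csv")
        bundle["landscape"] = summary
        bundle["reference_audit"] = la.audit_reference_table(config.w_edge)
        bundle["reference_audit"].to_csv(out / "reference_audit.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'landscape' failed: {e}") from e

    return bundle
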