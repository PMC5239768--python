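"""Functional groups, mass-from-size allometry, and per-trap community metrics.

Species are classified into the 2x2x2 functional cells {tunneller, roller} x
{diurnal, nocturnal} x {large, small}.  Mean dry mass for species that could
not be weighed is extrapolated from body size (length x width, mm^2) by a
log-log allometric regression on the weighed species.  Per-trap metrics are
richness, total abundance, biomass (sum over species of mean mass x count)
and per-group abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import group_label

__all__ = ["body_size", "extrapolate_mass", "trap_metrics"]


def body_size(length_mm, width_mm):
    """Body size as length x width (mm^2); inputs must be positive."""
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("length and width must be positive")
    out = length * width
    return float(out) if out.ndim == 0 else out


def extrapolate_mass(traits: pd.DataFrame, min_calibration: int = 5):
    """Fill missing mean masses from the size-mass allometry.

    Fits log(mass) = a + b log(size) on species with measured mass and
    predicts the rest.  Returns ``(traits_with_mass, r_squared)``; measured
    masses are never altered.
    """
    t = traits.copy()
    size = body_size(t["length_mm"], t["width_mm"])
    have = t["mean_mass_g"].notna() & (t["mean_mass_g"] > 0)
    if have.sum() < min_calibration:
        raise ValueError(
            f"need >= {min_calibration} species with measured mass and size "
            f"to calibrate the allometry (got {int(have.sum())})"
        )
    X = sm.add_constant(np.log(size[have]))
    fit = sm.OLS(np.log(t.loc[have, "mean_mass_g"].to_numpy()), X).fit()
    a, b = fit.params
    missing = ~have
    t.loc[missing, "mean_mass_g"] = np.exp(a + b * np.log(size[missing.to_numpy()]))
    return t, float(fit.rsquared)


def trap_metrics(samples: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trap community metrics from long-format counts and a trait table.

    Returns one row per trap with richness, abundance, biomass_g, one
    ``abundance_<group>`` column per non-empty functional cell, and the
    trap's metadata (plot, habitat, distance, coordinates).  Every sampled
    species must be present in the trait table with a (possibly
    extrapolated) mass.
    """
    sampled = set(samples["species"].unique())
    known = set(traits["species"])
    missing = sorted(sampled - known)
    if missing:
        raise ValueError(f"species missing from traits table: {missing}")
    t = traits.set_index("species")
    if t.loc[sorted(sampled), "mean_mass_g"].isna().any():
        offenders = sorted(
            s for s in sampled if pd.isna(t.at[s, "mean_mass_g"])
        )
        raise ValueError(f"species without mass (run extrapolate_mass): {offenders}")

    df = samples.merge(traits[["species", "guild", "diel", "size_class", "mean_mass_g"]],
                       on="species", how="left")
    df["group"] = [
        group_label(g, d, s)
        for g, d, s in zip(df["guild"], df["diel"], df["size_class"])
    ]
    df["biomass_g"] = df["mean_mass_g"] * df["count"]

    meta_cols = [c for c in ("plot_id", "habitat", "distance_m", "x", "y")
                 if c in samples.columns]
    meta = samples.drop_duplicates("trap_id").set_index("trap_id")[meta_cols]

    grp = df.groupby("trap_id")
    out = pd.DataFrame(
        {
            "richness": grp.apply(
                lambda g: int((g["count"] > 0).sum()), include_groups=False
            ),
            "abundance": grp["count"].sum(),
            "biomass_g": grp["biomass_g"].sum(),
        }
    )
    by_group = (
        df.pivot_table(index="trap_id", columns="group", values="count",
                       aggfunc="sum", fill_value=0)
    )
    nonempty = [c for c in by_group.columns if by_group[c].sum() > 0]
    for c in nonempty:
        out[f"abundance_{c}"] = by_group[c]
    out = meta.join(out, how="left")
    metric_cols = out.columns.difference(meta_cols)
    out[metric_cols] = out[metric_cols].fillna(0)
    return out.reset_index().rename(columns={"index": "trap_id"})
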