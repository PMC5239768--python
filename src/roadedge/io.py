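"""CSV readers/writers and validation for the long-format trap tables.

Tables on disk: samples.csv (trap_id, plot_id, habitat, distance_m, x, y,
species, count — one row per trap x species), traits.csv, vegetation.csv.
Distances are metres, masses grams, areas km^2; units are embedded in the
column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import HABITATS

SAMPLE_COLUMNS = ["trap_id", "plot_id", "habitat", "distance_m", "x", "y",
                  "species", "count"]
TRAIT_COLUMNS = ["species", "guild", "diel", "size_class", "length_mm",
                 "width_mm", "mean_mass_g"]


class ValidationError(ValueError):
    pass


def read_samples(path) -> pd.DataFrame:
    """Read and validate a long-format trap-sample table."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"samples table missing columns: {missing}")
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValidationError(f"negative count at row(s) {list(bad[:5])}")
    if not np.allclose(df["count"], np.round(df["count"])):
        bad = df.index[df["count"] != np.round(df["count"])]
        raise ValidationError(f"non-integer count at row(s) {list(bad[:5])}")
    df["count"] = df["count"].astype(int)
    unknown = set(df["habitat"].unique()) - set(HABITATS)
    if unknown:
        raise ValidationError(f"unknown habitat level(s): {sorted(unknown)}")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"traits table missing columns: {missing}")
    for col in ("length_mm", "width_mm"):
        if (df[col] <= 0).any():
            raise ValidationError(f"non-positive {col} in traits table")
    return df


def read_vegetation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "trap_id" not in df.columns:
        raise ValidationError("vegetation table missing trap_id")
    return df


def widen_counts(samples: pd.DataFrame) -> pd.DataFrame:
    """Long samples -> wide trap x species count matrix."""
    return samples.pivot_table(index="trap_id", columns="species",
                               values="count", aggfunc="sum", fill_value=0)


def flatten_counts(wide: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Wide trap x species matrix + per-trap metadata -> long samples."""
    long = wide.stack().rename("count").reset_index()
    long.columns = ["trap_id", "species", "count"]
    return meta.merge(long, on="trap_id")


def read_config(path) -> dict:
    """Plain-text key=value configuration; values parsed as int/float/str."""
    cfg = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        for cast in (int, float):
            try:
                cfg[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            cfg[key] = val
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in cfg.items())
    )
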