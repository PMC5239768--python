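"""Synthetic trap-survey generator for road-edge community studies.

Emulates a baited-pitfall design along unpaved logging roads: plots of six
traps at fixed distances from the road edge, interior transects deeper in the
logged forest, and reference transects in primary forest.  Counts are drawn
from a negative-binomial model whose log mean follows a two-segment
(breakpoint) function of distance from the edge, with log-normal plot-level
random intercepts; species are partitioned into the eight behavioural
functional groups (guild x diel activity x size class) used for dung beetles.

Everything is seeded and reproducible: fixed seed => bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nb import nb_rvs

HABITATS = ("road_edge", "interior", "primary")

GUILDS = ("tunneller", "roller")
DIELS = ("diurnal", "nocturnal")
SIZES = ("large", "small")

#: the eight functional-group cells, in reporting order
FUNCTIONAL_GROUPS = tuple(
    (g, d, s) for s in SIZES for d in DIELS for g in GUILDS
)


def group_label(guild: str, diel: str, size: str) -> str:
    return f"{size}_{diel}_{guild}"


@dataclass
class StudyDesign:
    """Sampling layout: road-edge plots, interior and primary transects.

    Defaults reproduce the reference design: 24 edge plots x 6 distances
    (144 traps), 58 interior traps on 14 transects at 170-550 m, and 60
    primary-forest traps on 12 transects of five.
    """

    n_edge_plots: int = 24
    edge_distances_m: tuple = (0, 6, 12, 25, 50, 100)
    n_interior_transects: int = 14
    n_interior_five_trap: int = 2  # remaining transects carry 4 traps
    interior_distances_4: tuple = (170, 270, 370, 470)
    interior_distances_5: tuple = (170, 265, 360, 455, 550)
    n_primary_transects: int = 12
    n_primary_traps_per_transect: int = 5
    min_trap_spacing_m: float = 50.0
    plot_spacing_m: float = 6000.0

    def validate(self) -> None:
        d = list(self.edge_distances_m)
        if any(x < 0 for x in d):
            raise ValueError("edge distances must be non-negative")
        if d != sorted(d) or len(set(d)) != len(d):
            raise ValueError("edge distances must be strictly increasing")
        for dl in (self.interior_distances_4, self.interior_distances_5):
            if list(dl) != sorted(dl) or any(x < 0 for x in dl):
                raise ValueError("interior distances must be sorted and non-negative")
        if self.n_interior_five_trap > self.n_interior_transects:
            raise ValueError("more five-trap transects than transects")

    @property
    def n_edge_traps(self) -> int:
        return self.n_edge_plots * len(self.edge_distances_m)

    @property
    def n_interior_traps(self) -> int:
        n5 = self.n_interior_five_trap
        return n5 * len(self.interior_distances_5) + (
            self.n_interior_transects - n5
        ) * len(self.interior_distances_4)

    @property
    def n_primary_traps(self) -> int:
        return self.n_primary_transects * self.n_primary_traps_per_transect

    @property
    def n_traps(self) -> int:
        return self.n_edge_traps + self.n_interior_traps + self.n_primary_traps


def _stagger_offsets(n: int, spacing: float) -> np.ndarray:
    """Lateral offsets 0, +s, -s, +2s, -2s, ... (alternating sides).

    Successive traps sit on alternating sides of the line perpendicular to
    the road, so every pairwise lateral separation is >= ``spacing`` and the
    within-plot spacing constraint holds regardless of the distance steps.
    """
    off = np.empty(n)
    for k in range(n):
        m = (k + 1) // 2
        off[k] = spacing * m * (1 if k % 2 == 1 else -1) if k else 0.0
    return off


def generate_design(design: StudyDesign | None = None, seed: int = 0) -> pd.DataFrame:
    """Lay out trap locations for the study design.

    Returns a DataFrame with one row per trap: trap_id, plot_id, habitat,
    distance_m (NaN for primary forest, where distance-from-road is
    undefined), and planar coordinates x, y in metres.
    """
    design = design or StudyDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []

    # road runs along y = 0; edge plots spaced along it
    offs = _stagger_offsets(len(design.edge_distances_m), design.min_trap_spacing_m)
    for p in range(design.n_edge_plots):
        x0 = p * design.plot_spacing_m
        for k, d in enumerate(design.edge_distances_m):
            rows.append(
                dict(
                    trap_id=f"E{p:02d}T{k}",
                    plot_id=f"edge_{p:02d}",
                    habitat="road_edge",
                    distance_m=float(d),
                    x=x0 + offs[k],
                    y=float(d),
                )
            )

    for t in range(design.n_interior_transects):
        dists = (
            design.interior_distances_5
            if t < design.n_interior_five_trap
            else design.interior_distances_4
        )
        x0 = t * design.plot_spacing_m + design.plot_spacing_m / 2.0
        jit = rng.uniform(-10.0, 10.0, size=len(dists))
        for k, d in enumerate(dists):
            rows.append(
                dict(
                    trap_id=f"I{t:02d}T{k}",
                    plot_id=f"interior_{t:02d}",
                    habitat="interior",
                    distance_m=float(d),
                    x=x0 + jit[k],
                    y=float(d),
                )
            )

    for t in range(design.n_primary_transects):
        x0 = -(t + 1) * 4500.0
        jit = rng.uniform(-10.0, 10.0, size=design.n_primary_traps_per_transect)
        for k in range(design.n_primary_traps_per_transect):
            rows.append(
                dict(
                    trap_id=f"P{t:02d}T{k}",
                    plot_id=f"primary_{t:02d}",
                    habitat="primary",
                    distance_m=np.nan,
                    x=x0 + jit[k],
                    y=100.0 * k,
                )
            )

    return pd.DataFrame(rows)


def _log_series_weights(n_species: int, x: float = 0.97) -> np.ndarray:
    r = np.arange(1, n_species + 1, dtype=float)
    w = x**r / r
    return w / w.sum()


@dataclass
class CommunityModel:
    """Data-generating model for per-trap, per-species counts.

    Log mean for species s (group g) at distance d:

        log mu = beta0_s + u_plot + edge_slope_g * min(d, psi)
                 + post_break_slope_g * max(d - psi, 0)

    so ``edge_slope`` is the pre-breakpoint gradient and
    ``post_break_slope`` the absolute gradient beyond the breakpoint
    (0 = flat).  Counts are NB2 with size ``theta``; primary-forest traps
    use the interior mean times ``exp(primary_log_offset)``.
    """

    n_species: int = 74
    interior_total_mean: float = 129.3  # expected individuals per interior trap
    edge_slope: dict = field(default_factory=dict)  # per group label, per m
    post_break_slope: dict = field(default_factory=dict)
    breakpoint_m: float = 130.0
    theta: float = 1.5
    plot_random_sd: float = 0.3
    primary_log_offset: float = 0.13
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        default_slope = 0.012
        for g, d, s in FUNCTIONAL_GROUPS:
            lab = group_label(g, d, s)
            if lab not in self.edge_slope:
                # small diurnal rollers are edge-insensitive by default
                self.edge_slope[lab] = (
                    0.0 if (g, d, s) == ("roller", "diurnal", "small") else default_slope
                )
            self.post_break_slope.setdefault(lab, 0.0)

    def species_table(self) -> pd.DataFrame:
        """Species ids, group assignment and baseline log means.

        Baselines follow a right-skewed log-series rank-abundance curve
        scaled so expected interior trap totals equal
        ``interior_total_mean``.
        """
        rng = np.random.default_rng(self.seed)
        w = _log_series_weights(self.n_species)
        cells = [FUNCTIONAL_GROUPS[i % 8] for i in range(self.n_species)]
        rng.shuffle(cells)
        recs = []
        for i, (g, d, s) in enumerate(cells):
            lab = group_label(g, d, s)
            interior_mean = self.interior_total_mean * w[i]
            b0 = np.log(interior_mean) - self.edge_slope[lab] * self.breakpoint_m
            recs.append(
                dict(
                    species=f"sp{i + 1:03d}",
                    guild=g,
                    diel=d,
                    size_class=s,
                    group=lab,
                    baseline_log_mean=b0,
                )
            )
        return pd.DataFrame(recs)


def generate_counts(
    locations: pd.DataFrame, model: CommunityModel | None = None
) -> pd.DataFrame:
    """Draw per-trap, per-species NB counts for the given trap locations.

    Returns a long-format table (one row per trap x species, zeros kept):
    trap_id, plot_id, habitat, distance_m, x, y, species, count.
    """
    model = model or CommunityModel()
    if model.theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(model.seed)
    sp = model.species_table()

    plots = locations["plot_id"].unique()
    u = dict(
        zip(plots, rng.normal(0.0, model.plot_random_sd, size=len(plots)))
    )

    b0 = sp["baseline_log_mean"].to_numpy()
    b1 = sp["group"].map(model.edge_slope).to_numpy()
    b2 = sp["group"].map(model.post_break_slope).to_numpy()
    psi = model.breakpoint_m

    primary = (locations["habitat"] == "primary").to_numpy()
    d = locations["distance_m"].to_numpy(dtype=float)
    d = np.where(primary, psi, d)  # placeholder; primary handled below
    pre = np.minimum(d, psi)[:, None]
    post = np.maximum(d - psi, 0.0)[:, None]
    eta = b0[None, :] + b1[None, :] * pre + b2[None, :] * post
    eta[primary] = b0[None, :] + b1[None, :] * psi + model.primary_log_offset
    u_trap = locations["plot_id"].map(u).to_numpy()
    eta = eta + u_trap[:, None]
    counts = nb_rvs(rng, np.exp(eta), model.theta)

    n_traps, n_sp = counts.shape
    long = pd.DataFrame(
        {
            "trap_id": np.repeat(locations["trap_id"].to_numpy(), n_sp),
            "plot_id": np.repeat(locations["plot_id"].to_numpy(), n_sp),
            "habitat": np.repeat(locations["habitat"].to_numpy(), n_sp),
            "distance_m": np.repeat(locations["distance_m"].to_numpy(), n_sp),
            "x": np.repeat(locations["x"].to_numpy(), n_sp),
            "y": np.repeat(locations["y"].to_numpy(), n_sp),
            "species": np.tile(sp["species"].to_numpy(), n_traps),
            "count": counts.ravel(),
        }
    )
    return long


def generate_traits(
    model: CommunityModel | None = None,
    seed: int = 1,
    mass_allometry=(0.0003, 1.35),
    frac_missing_mass: float = 0.3,
) -> pd.DataFrame:
    """Trait table: guild/diel/size labels, body measurements, mean dry mass.

    Body mass follows the allometry mass = a * size**b (size = length x width
    in mm^2) with multiplicative log-normal noise; a fraction of species have
    missing mass to exercise the extrapolation step.
    """
    model = model or CommunityModel()
    sp = model.species_table()
    rng = np.random.default_rng(seed)
    n = len(sp)
    large = (sp["size_class"] == "large").to_numpy()
    length = np.where(
        large, rng.uniform(12.0, 30.0, n), rng.uniform(3.0, 11.0, n)
    )
    width = length * rng.uniform(0.45, 0.65, n)
    size = length * width
    a, b = mass_allometry
    mass = a * size**b * np.exp(rng.normal(0.0, 0.10, n))
    missing = rng.random(n) < frac_missing_mass
    mass = np.where(missing, np.nan, mass)
    return pd.DataFrame(
        {
            "species": sp["species"],
            "guild": sp["guild"],
            "diel": sp["diel"],
            "size_class": sp["size_class"],
            "length_mm": np.round(length, 1),
            "width_mm": np.round(width, 1),
            "mean_mass_g": mass,
        }
    )


#: the eight vegetation / micro-habitat measures emulated, with
#: (edge value, interior plateau value) on each variable's natural scale
VEGETATION_PROFILES = {
    "successional_vegetation": (8.0, 1.5),
    "ground_cover": (25.0, 60.0),
    "canopy_cover": (40.0, 85.0),
    "n_large_trees": (1.0, 6.0),
    "n_small_trees": (4.0, 12.0),
    "height_large_trees_m": (12.0, 28.0),
    "height_small_trees_m": (4.0, 9.0),
    "girth_large_trees_cm": (60.0, 150.0),
}


def generate_vegetation(
    locations: pd.DataFrame,
    breakpoint_m: float = 34.0,
    seed: int = 2,
    noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Per-trap vegetation measures with a shared structural breakpoint.

    Each measure moves linearly from its road-edge value to its interior
    plateau over [0, breakpoint_m] and is flat beyond; early-successional
    vegetation declines with distance while tree cover/size measures
    increase.  Gaussian noise with SD = noise_sd x plateau value.
    """
    rng = np.random.default_rng(seed)
    d = locations["distance_m"].to_numpy(dtype=float)
    d = np.where(np.isnan(d), breakpoint_m * 10, d)  # primary: deep interior
    frac = np.clip(d / breakpoint_m, 0.0, 1.0)
    out = {"trap_id": locations["trap_id"].to_numpy()}
    for name, (v_edge, v_int) in VEGETATION_PROFILES.items():
        mean = v_edge + (v_int - v_edge) * frac
        noise = rng.normal(0.0, noise_sd * abs(v_int), size=len(d))
        out[name] = mean + noise
    return pd.DataFrame(out)
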