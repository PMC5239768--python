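"""Generator contracts: design layout, count model, vegetation gradients."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from roadedge import synthetic_data as sd
from roadedge._nb import profile_theta_mle
from roadedge.gradient_models import fit_piecewise

from conftest import make_locations


class TestDesign:
    def test_default_trap_counts(self):
        locs = sd.generate_design(seed=0)
        assert (locs["habitat"] == "road_edge").sum() == 144
        assert (locs["habitat"] == "interior").sum() == 58
        assert (locs["habitat"] == "primary").sum() == 60
        assert len(locs) == 262

    def test_single_plot_single_distance(self):
        d = sd.StudyDesign(n_edge_plots=1, edge_distances_m=(0,),
                           n_interior_transects=0, n_interior_five_trap=0,
                           n_primary_transects=0)
        locs = sd.generate_design(d, seed=0)
        assert len(locs) == 1
        assert locs.loc[0, "distance_m"] == 0.0

    def test_every_edge_plot_covers_every_distance(self):
        locs = sd.generate_design(seed=0)
        edge = locs[locs["habitat"] == "road_edge"]
        per_plot = edge.groupby("plot_id")["distance_m"].apply(sorted)
        for dists in per_plot:
            assert dists == [0.0, 6.0, 12.0, 25.0, 50.0, 100.0]

    def test_within_plot_spacing_at_least_50m(self):
        locs = sd.generate_design(seed=0)
        for _, plot in locs.groupby("plot_id"):
            if len(plot) < 2:
                continue
            assert pdist(plot[["x", "y"]].to_numpy()).min() >= 50.0 - 1e-9

    @pytest.mark.parametrize("bad", [(6, 0, 12), (-5, 0, 6)])
    def test_invalid_distance_list_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.generate_design(sd.StudyDesign(edge_distances_m=bad), seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = sd.generate_design(seed=3)
        b = sd.generate_design(seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCounts:
    def test_counts_are_nonnegative_integers(self, default_samples):
        assert (default_samples["count"] >= 0).all()
        assert default_samples["count"].dtype.kind == "i"

    def test_deterministic_for_fixed_seed(self, default_locations):
        a = sd.generate_counts(default_locations, sd.CommunityModel(seed=5))
        b = sd.generate_counts(default_locations, sd.CommunityModel(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            sd.CommunityModel(theta=0.0)

    def test_flat_model_mean_converges_to_baseline(self):
        # beta1 = beta2 = 0, no plot effect: trap means converge to exp(beta0)
        locs = make_locations([25.0] * 10_000)
        locs["plot_id"] = locs["trap_id"]  # one trap per plot, sd irrelevant
        slopes = {sd.group_label(g, d, s): 0.0 for g, d, s in sd.FUNCTIONAL_GROUPS}
        model = sd.CommunityModel(
            n_species=1, interior_total_mean=8.0, edge_slope=slopes,
            plot_random_sd=0.0, theta=2.0, seed=1,
        )
        counts = sd.generate_counts(locs, model)["count"].to_numpy()
        mu, th = 8.0, 2.0
        mc_se = np.sqrt((mu + mu**2 / th) / len(counts))
        assert abs(counts.mean() - mu) < 3 * mc_se

    def test_large_theta_poisson_limit(self):
        locs = make_locations([50.0] * 5000)
        slopes = {sd.group_label(g, d, s): 0.0 for g, d, s in sd.FUNCTIONAL_GROUPS}
        model = sd.CommunityModel(
            n_species=1, interior_total_mean=10.0, edge_slope=slopes,
            plot_random_sd=0.0, theta=1e7, seed=2,
        )
        c = sd.generate_counts(locs, model)["count"].to_numpy()
        ratio = c.var(ddof=1) / c.mean()
        assert abs(ratio - 1.0) < 0.1

    def test_dispersion_recovery(self):
        # theta = 1.5 recovered within +/-20% from 500 single-species traps
        locs = make_locations([100.0] * 500)
        slopes = {sd.group_label(g, d, s): 0.0 for g, d, s in sd.FUNCTIONAL_GROUPS}
        model = sd.CommunityModel(
            n_species=1, interior_total_mean=12.0, edge_slope=slopes,
            plot_random_sd=0.0, theta=1.5, seed=42,
        )
        y = sd.generate_counts(locs, model)["count"].to_numpy()
        theta_hat = profile_theta_mle(y, np.full_like(y, y.mean(), dtype=float))
        assert 0.8 * 1.5 <= theta_hat <= 1.2 * 1.5

    def test_group_slope_ordering_realized(self):
        # sloped groups are depressed at the edge; the flat group is not
        locs = sd.generate_design(seed=0)
        model = sd.CommunityModel(seed=9, plot_random_sd=0.0)
        samples = sd.generate_counts(locs, model)
        sp = model.species_table()
        merged = samples.merge(sp[["species", "group"]], on="species")
        edge0 = merged[(merged["habitat"] == "road_edge") & (merged["distance_m"] == 0)]
        interior = merged[merged["habitat"] == "interior"]
        for grp, b1 in model.edge_slope.items():
            e = edge0[edge0["group"] == grp]["count"].mean()
            i = interior[interior["group"] == grp]["count"].mean()
            if b1 > 0:
                assert e < i
            else:
                assert abs(e - i) < 0.5 * max(i, 1.0)


class TestVegetation:
    def test_zero_noise_equal_distance_equal_values(self):
        locs = make_locations([0, 6, 6, 100])
        veg = sd.generate_vegetation(locs, seed=3, noise_sd=0.0)
        v6 = veg.iloc[[1, 2]].drop(columns="trap_id")
        assert np.allclose(v6.iloc[0], v6.iloc[1])

    def test_successional_declines_with_distance(self, default_locations):
        veg = sd.generate_vegetation(default_locations, seed=4)
        merged = default_locations.merge(veg, on="trap_id")
        edge = merged[merged["habitat"] == "road_edge"]
        m0 = edge.loc[edge["distance_m"] == 0, "successional_vegetation"].mean()
        m100 = edge.loc[edge["distance_m"] == 100, "successional_vegetation"].mean()
        assert m0 > m100

    def test_noiseless_breakpoint_recovered_by_piecewise_fit(self):
        dists = list(range(0, 121, 5))
        locs = make_locations(dists)
        veg = sd.generate_vegetation(locs, breakpoint_m=34.0, seed=5, noise_sd=0.0)
        fit = fit_piecewise(
            veg["canopy_cover"].to_numpy(),
            locs["distance_m"].to_numpy(),
            gaussian=True, grid_step=1.0, se_boot=0,
        )
        assert abs(fit.psi - 34.0) <= 1.0

    def test_deterministic_for_fixed_seed(self, default_locations):
        a = sd.generate_vegetation(default_locations, seed=6)
        b = sd.generate_vegetation(default_locations, seed=6)
        pd.testing.assert_frame_equal(a, b)
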