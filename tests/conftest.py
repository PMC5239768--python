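import numpy as np
import pandas as pd
import pytest

from roadedge import synthetic_data as sd


@pytest.fixture(scope="session")
def default_locations():
    return sd.generate_design(sd.StudyDesign(), seed=11)


@pytest.fixture(scope="session")
def default_samples(default_locations):
    model = sd.CommunityModel(seed=7)
    return sd.generate_counts(default_locations, model)


@pytest.fixture(scope="session")
def default_traits():
    return sd.generate_traits(sd.CommunityModel(seed=7), seed=8)


def make_locations(distances, n_plots=1, habitat="road_edge"):
    """Minimal hand-built trap table for generator-level tests."""
    rows = []
    for p in range(n_plots):
        for k, d in enumerate(distances):
            rows.append(
                dict(trap_id=f"p{p}t{k}", plot_id=f"plot{p}", habitat=habitat,
                     distance_m=float(d), x=1000.0 * p + 60.0 * k, y=float(d))
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
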