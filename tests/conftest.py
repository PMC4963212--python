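import numpy as np
import pandas as pd
import pytest

from curvetracks import (TrackSet, WalkModel, simulate_walk)
from curvetracks.surfaces import Cylinder, Sphere


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_tracks():
    """Two short tracks with known steps."""
    df = pd.DataFrame({
        "track_id": ["a"] * 3 + ["b"] * 4,
        "t": [0, 1, 2, 0, 1, 2, 3],
        "x": [0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0],
        "y": [0.0, 0.0, 1.0, 0.0, 1.0, 1.0, 2.0],
        "z": [0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0],
    })
    return TrackSet.from_dataframe(df)


@pytest.fixture(scope="session")
def cylinder_points():
    """2000 random points on a 300-degree sector of a unit cylinder."""
    r = np.random.default_rng(0)
    th = r.uniform(-2.6, 2.6, 2000)
    z = r.uniform(-2.0, 2.0, 2000)
    return np.column_stack([np.cos(th), np.sin(th), z]), th, z


def cap_region(deg):
    c = np.cos(np.deg2rad(deg))
    axis = np.array([0.0, 0.0, 1.0])

    def region(p):
        u = p / np.linalg.norm(p, axis=-1, keepdims=True)
        return u @ axis >= c
    return region


@pytest.fixture(scope="session")
def hemisphere_brownian():
    """Brownian walk on the dome preset (50 tracks x 200 steps)."""
    return simulate_walk(Sphere(radius=1.0), WalkModel(step_length=0.02),
                         n_tracks=50, n_steps=200, seed=1,
                         start_region=cap_region(60))


@pytest.fixture(scope="session")
def plane_brownian_small():
    from curvetracks.surfaces import Plane
    return simulate_walk(Plane(extent=4.0), WalkModel(step_length=0.05),
                         n_tracks=20, n_steps=100, seed=3)
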