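import numpy as np
import pytest

from gridtraj.dataset_builder import stack_dataset
from gridtraj.grid_encoding import BinaryGrid, GridSpec, encode_trips
from gridtraj.synthetic_trips import SimConfig, generate_cohort
from gridtraj.trajectory_io import GPSPoint, Trip


def make_trip(coords, trip_id="t0", label=None):
    """Trip from a list of (lat, lon) pairs."""
    return Trip(trip_id, [GPSPoint(lat, lon) for lat, lon in coords], label)


def random_trip(rng, n_points=50, trip_id="t0", label=None):
    lat0 = rng.uniform(-60, 60)
    lon0 = rng.uniform(-150, 150)
    lats = lat0 + rng.normal(0, 0.01, n_points)
    lons = lon0 + rng.normal(0, 0.01, n_points)
    return Trip(trip_id, [GPSPoint(a, o) for a, o in zip(lats, lons)], label)


def random_grid(rng, H=64, W=64, density=0.1, trip_id="g0", label="normal"):
    values = (rng.random((H, W)) < density).astype(np.uint8)
    values[H // 2, W // 2] = 1  # keep at least one visited cell
    return BinaryGrid(values, GridSpec(H, W), trip_id, label)


@pytest.fixture(scope="session")
def small_cohort():
    """30 labeled trips (20 normal / 10 abnormal), default conditions."""
    return generate_cohort(20, 10, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """The small cohort encoded at 32x32 and stacked."""
    return stack_dataset(encode_trips(small_cohort, GridSpec(32, 32)))
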