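import dataclasses

import numpy as np
import pytest
from shapely.geometry import Polygon

from fcaccess.core import PointLocation, Zone
from fcaccess.demand import AGE_BINS, DemandUnit, load_default_schedules
from fcaccess.engine import SupplySite
from fcaccess.synth import generate_city, scenario_presets


@pytest.fixture(scope="session")
def schedules():
    return load_default_schedules()


@pytest.fixture(scope="session")
def montreal_schedule(schedules):
    return schedules["montreal"]


def make_random_instance(rng, n_clinics, n_zones, extent=5000.0, schedule=None):
    """A random small city: uniform clinics and zone centroids in a square."""
    supply = [
        SupplySite(
            id=f"C{j}",
            location=PointLocation(rng.uniform(0, extent), rng.uniform(0, extent)),
            S_j=float(rng.integers(1, 4)),
            P_j=int(rng.integers(1, 12)),
        )
        for j in range(n_clinics)
    ]
    demand = []
    for k in range(n_zones):
        counts = {b: int(rng.integers(0, 120)) for b in AGE_BINS}
        unit = DemandUnit(
            zone=Zone(
                id=f"Z{k}",
                centroid=PointLocation(rng.uniform(0, extent), rng.uniform(0, extent)),
            ),
            age_counts=counts,
        )
        if schedule is not None:
            unit = unit.with_potential_users(schedule)
        demand.append(unit)
    return supply, demand


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def grid_zones(rows, cols, size=1.0):
    """rows x cols tessellation of unit squares as Zone objects."""
    zones = []
    for r in range(rows):
        for c in range(cols):
            poly = Polygon(
                [
                    (c * size, r * size),
                    ((c + 1) * size, r * size),
                    ((c + 1) * size, (r + 1) * size),
                    (c * size, (r + 1) * size),
                ]
            )
            zones.append(Zone.from_polygon(f"{r}-{c}", poly))
    return zones


@pytest.fixture(scope="session")
def montreal_like_city():
    """One shared montreal_like instance (the expensive fixture)."""
    cfg = dataclasses.replace(scenario_presets()["montreal_like"], seed=7)
    return generate_city(cfg)
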