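"""Seeded synthetic-city generator.

Produces a complete test instance — clinics clustered around a central
business district (CBD), a rectangular grid of demand zones with
age-structured populations, and a grid street network — so the whole
accessibility pipeline runs without any external data.

The defaults of the ``montreal_like`` preset emulate a large island city:
~3,100 zones of a few hundred residents each (lognormal totals, median
~542, mean ~586), 236 clinics holding 1,344 physicians in total on
average, clinics drawn mostly from a Gaussian around the CBD so their
point pattern is clustered (nearest-neighbour index < 1).
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import PointLocation, StreetNetwork, Zone
from .demand import AGE_BINS, DemandUnit, load_default_schedules
from .engine import SupplySite

__all__ = ["CityConfig", "SyntheticCity", "generate_city", "scenario_presets"]


def _age_profile() -> np.ndarray:
    with resources.files("fcaccess.data").joinpath("age_profile.csv").open() as fh:
        df = pd.read_csv(fh)
    prof = df.set_index("age_group")["share"].reindex(list(AGE_BINS))
    return prof.to_numpy(dtype=float)


@dataclasses.dataclass
class CityConfig:
    """Parameters of one synthetic city.

    rows x cols zones, each a square cell of ``cell_size`` meters.
    ``clinic_clustering`` is the fraction of clinics drawn from a Gaussian
    around the CBD (city center) with sd ``cbd_sigma``; the rest are
    uniform. Physician counts follow 1 + Poisson(physician_lambda).
    Per-zone totals are lognormal with the given median and log-sd; the
    age mix is Dirichlet around the packaged mean profile with the given
    concentration. ``network_spacing`` is the street-grid mesh in meters.
    """

    rows: int = 10
    cols: int = 10
    cell_size: float = 400.0
    n_clinics: int = 10
    clinic_clustering: float = 0.8
    cbd_sigma_frac: float = 0.12  # Gaussian sd as a fraction of city diagonal
    physician_lambda: float = 4.0
    pop_median: float = 542.0
    pop_log_sigma: float = 0.395
    age_concentration: float = 100.0
    network_spacing: float = 400.0
    schedule: str = "montreal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.n_clinics) < 1:
            raise ValueError("rows, cols and n_clinics must be >= 1")
        if self.cell_size <= 0 or self.network_spacing <= 0:
            raise ValueError("cell_size and network_spacing must be > 0")
        if not 0.0 <= self.clinic_clustering <= 1.0:
            raise ValueError("clinic_clustering must be in [0, 1]")

    @property
    def width(self) -> float:
        return self.cols * self.cell_size

    @property
    def height(self) -> float:
        return self.rows * self.cell_size


@dataclasses.dataclass
class SyntheticCity:
    supply: list  # of SupplySite
    demand: list  # of DemandUnit
    zones: list  # of Zone
    network: StreetNetwork
    config: CityConfig

    @property
    def cbd(self) -> PointLocation:
        return PointLocation(self.config.width / 2.0, self.config.height / 2.0)


def generate_city(config: CityConfig) -> SyntheticCity:
    """Deterministic (seeded) city: zones, demand, clinics, street grid."""
    root = np.random.default_rng(config.seed)
    # independent substreams so adding a component never shifts the others
    rng_pop, rng_age, rng_clinic, rng_phys = root.spawn(4)

    zones: list[Zone] = []
    demand: list[DemandUnit] = []
    profile = _age_profile()
    schedule = load_default_schedules()[config.schedule]
    n_zones = config.rows * config.cols
    totals = np.maximum(
        1.0,
        np.round(
            config.pop_median
            * np.exp(rng_pop.normal(0.0, config.pop_log_sigma, size=n_zones))
        ),
    )
    mixes = rng_age.dirichlet(profile * config.age_concentration, size=n_zones)
    k = 0
    for r in range(config.rows):
        for c in range(config.cols):
            x0, y0 = c * config.cell_size, r * config.cell_size
            poly = Polygon(
                [
                    (x0, y0),
                    (x0 + config.cell_size, y0),
                    (x0 + config.cell_size, y0 + config.cell_size),
                    (x0, y0 + config.cell_size),
                ]
            )
            zone = Zone.from_polygon(f"Z{k:05d}", poly)
            zones.append(zone)
            # integer age counts that sum exactly to the zone total
            raw = mixes[k] * totals[k]
            counts = np.floor(raw).astype(int)
            short = int(totals[k] - counts.sum())
            order = np.argsort(-(raw - counts))
            counts[order[:short]] += 1
            unit = DemandUnit(
                zone=zone, age_counts=dict(zip(AGE_BINS, counts.tolist()))
            ).with_potential_users(schedule)
            demand.append(unit)
            k += 1

    n_clustered = int(round(config.clinic_clustering * config.n_clinics))
    sigma = config.cbd_sigma_frac * float(np.hypot(config.width, config.height))
    cx, cy = config.width / 2.0, config.height / 2.0
    pts = []
    while len(pts) < n_clustered:
        x, y = rng_clinic.normal([cx, cy], sigma)
        if 0 <= x <= config.width and 0 <= y <= config.height:
            pts.append((x, y))
    for _ in range(config.n_clinics - n_clustered):
        pts.append(
            (
                rng_clinic.uniform(0, config.width),
                rng_clinic.uniform(0, config.height),
            )
        )
    physicians = 1 + rng_phys.poisson(config.physician_lambda, size=config.n_clinics)
    supply = [
        SupplySite(
            id=f"C{j:04d}",
            location=PointLocation(float(x), float(y)),
            S_j=1.0,
            P_j=int(p),
        )
        for j, ((x, y), p) in enumerate(zip(pts, physicians))
    ]

    network = _grid_network(config)
    return SyntheticCity(
        supply=supply, demand=demand, zones=zones, network=network, config=config
    )


def _grid_network(config: CityConfig) -> StreetNetwork:
    """Connected street grid spanning the city, mesh = network_spacing."""
    s = config.network_spacing
    nx_ = int(np.floor(config.width / s)) + 1
    ny_ = int(np.floor(config.height / s)) + 1
    nodes = {}
    for iy in range(ny_):
        for ix in range(nx_):
            nodes[f"N{ix}_{iy}"] = PointLocation(ix * s, iy * s)
    edges = []
    for iy in range(ny_):
        for ix in range(nx_):
            if ix + 1 < nx_:
                edges.append((f"N{ix}_{iy}", f"N{ix + 1}_{iy}", s))
            if iy + 1 < ny_:
                edges.append((f"N{ix}_{iy}", f"N{ix}_{iy + 1}", s))
    return StreetNetwork(nodes, edges)


def scenario_presets() -> dict[str, CityConfig]:
    """Named configurations.

    toy9: 3x3 zones, 2 clinics — an end-to-end smoke instance.
    dense_small: small tight city where every clinic has demand and every
        zone has a clinic within 500 m (full coverage at all standard
        thresholds), used for conservation checks.
    montreal_like: 56x56 = 3,136 zones of ~400 m, 236 clinics with a
        physician mean near 1344/236, clustered around the CBD.
    """
    return {
        "toy9": CityConfig(
            rows=3, cols=3, cell_size=400.0, n_clinics=2, physician_lambda=3.0
        ),
        "dense_small": CityConfig(
            rows=6,
            cols=6,
            cell_size=100.0,
            n_clinics=9,
            clinic_clustering=0.0,
            network_spacing=100.0,
        ),
        "montreal_like": CityConfig(
            rows=56,
            cols=56,
            cell_size=400.0,
            n_clinics=236,
            clinic_clustering=0.8,
            physician_lambda=1344.0 / 236.0 - 1.0,
            network_spacing=400.0,
        ),
    }
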