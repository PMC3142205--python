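"""Readers and writers: CSV tables and GeoJSON (RFC 7946) layers.

Coordinates are planar meters throughout. GeoJSON layers may declare a
``crs_units`` foreign member; ``"degrees"`` (geographic lon/lat) is
rejected because every distance threshold in this package is metric.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape

from .core import PointLocation, StreetNetwork, Zone
from .demand import AGE_BINS, DemandUnit, UtilizationSchedule
from .engine import AccessibilityScores, SupplySite

__all__ = [
    "RunConfig",
    "read_supply",
    "write_supply",
    "read_demand",
    "write_demand",
    "read_zones",
    "write_zones",
    "read_network",
    "write_network",
    "read_schedule",
    "write_scores_csv",
    "write_scores_geojson",
]

_AGE_COLS = {b: "pop_" + b.replace("-", "_").replace("+", "_plus") for b in AGE_BINS}

DEFAULT_THRESHOLDS = (500.0, 1000.0, 2000.0, 3000.0)


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a full workflow run."""

    supply: str | None = None
    demand: str | None = None
    zones: str | None = None
    network: str | None = None
    metric: str = "euclidean"  # "euclidean" | "network"
    thresholds: tuple = DEFAULT_THRESHOLDS
    methods: tuple = ("conventional", "optimized")
    schedule: str = "montreal"
    output_dir: str = "fcaccess_out"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        if any(t <= 0 for t in th) or list(th) != sorted(set(th)):
            raise ValueError("thresholds must be positive and strictly increasing")
        if not self.methods:
            raise ValueError("at least one method required")
        self.thresholds = th
        self.methods = tuple(self.methods)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_unique(ids: pd.Series, kind: str, path) -> None:
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate {kind} id {dup.iloc[0]!r}")


def read_supply(path: str | Path) -> list[SupplySite]:
    """Supply CSV: clinic_id, x, y, physicians[, capacity]."""
    df = pd.read_csv(path)
    _require_columns(df, ["clinic_id", "x", "y", "physicians"], path)
    _check_unique(df["clinic_id"].astype(str), "clinic", path)
    sites = []
    for row in df.itertuples(index=True):
        try:
            sites.append(
                SupplySite(
                    id=str(row.clinic_id),
                    location=PointLocation(float(row.x), float(row.y)),
                    S_j=float(getattr(row, "capacity", 1.0)),
                    P_j=int(row.physicians),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}, row {row.Index + 2}: {e}") from e
    return sites


def write_supply(sites, path: str | Path) -> None:
    pd.DataFrame(
        {
            "clinic_id": [s.id for s in sites],
            "x": [s.location.x for s in sites],
            "y": [s.location.y for s in sites],
            "physicians": [s.P_j for s in sites],
            "capacity": [s.S_j for s in sites],
        }
    ).to_csv(path, index=False)


def read_demand(
    path: str | Path, schedule: UtilizationSchedule | None = None
) -> list[DemandUnit]:
    """Demand CSV: zone_id, x, y, pop_0_14, ..., pop_80_plus."""
    df = pd.read_csv(path)
    _require_columns(df, ["zone_id", "x", "y", *_AGE_COLS.values()], path)
    _check_unique(df["zone_id"].astype(str), "zone", path)
    units = []
    for row in df.itertuples(index=True):
        counts = {b: getattr(row, col) for b, col in _AGE_COLS.items()}
        try:
            unit = DemandUnit(
                zone=Zone(
                    id=str(row.zone_id),
                    centroid=PointLocation(float(row.x), float(row.y)),
                ),
                age_counts=counts,
            )
        except ValueError as e:
            raise ValueError(f"{path}, row {row.Index + 2}: {e}") from e
        if schedule is not None:
            unit = unit.with_potential_users(schedule)
        units.append(unit)
    return units


def write_demand(units, path: str | Path) -> None:
    rows = {
        "zone_id": [u.id for u in units],
        "x": [u.zone.centroid.x for u in units],
        "y": [u.zone.centroid.y for u in units],
    }
    for b, col in _AGE_COLS.items():
        rows[col] = [u.age_counts.get(b, 0) for u in units]
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_units(obj, path) -> None:
    if obj.get("crs_units") == "degrees":
        raise ValueError(
            f"{path}: geographic (degree) coordinates; project to planar meters first"
        )


def read_zones(path: str | Path) -> list[Zone]:
    """Zone polygons from a GeoJSON FeatureCollection with ``zone_id``."""
    with open(path) as fh:
        gj = json.load(fh)
    _check_units(gj, path)
    zones = []
    seen = set()
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        zid = str(props.get("zone_id", k))
        if zid in seen:
            raise ValueError(f"{path}: duplicate zone id {zid!r}")
        seen.add(zid)
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"{path}: zone {zid!r} is {geom.geom_type}, not a polygon")
        zones.append(Zone.from_polygon(zid, geom))
    if not zones:
        raise ValueError(f"{path}: no features")
    return zones


def write_zones(zones, path: str | Path, properties: dict | None = None) -> None:
    """Zones to GeoJSON; ``properties`` maps zone id -> extra property dict."""
    feats = []
    for z in zones:
        props = {"zone_id": z.id}
        if properties and z.id in properties:
            props.update(properties[z.id])
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(
                    z.polygon
                    if z.polygon is not None
                    else Point(z.centroid.x, z.centroid.y)
                ),
            }
        )
    _dump_geojson(feats, path)


def _dump_geojson(features, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "crs_units": "meters", "features": features},
            fh,
            sort_keys=True,
            separators=(",", ":"),
        )
        fh.write("\n")


def read_network(nodes_path: str | Path, edges_path: str | Path) -> StreetNetwork:
    """Street network from a node/edge CSV pair.

    nodes CSV: node_id, x, y; edges CSV: from_id, to_id, length_m.
    """
    nd = pd.read_csv(nodes_path)
    _require_columns(nd, ["node_id", "x", "y"], nodes_path)
    _check_unique(nd["node_id"].astype(str), "node", nodes_path)
    ed = pd.read_csv(edges_path)
    _require_columns(ed, ["from_id", "to_id", "length_m"], edges_path)
    nodes = {
        str(r.node_id): PointLocation(float(r.x), float(r.y))
        for r in nd.itertuples()
    }
    edges = [
        (str(r.from_id), str(r.to_id), float(r.length_m)) for r in ed.itertuples()
    ]
    referenced = {n for u, v, _ in edges for n in (u, v)}
    unknown = referenced - set(nodes)
    if unknown:
        raise ValueError(f"{edges_path}: edges reference unknown nodes {sorted(unknown)[:5]}")
    return StreetNetwork(nodes, edges)


def write_network(network: StreetNetwork, nodes_path, edges_path) -> None:
    nodes = network.nodes
    pd.DataFrame(
        {
            "node_id": list(nodes),
            "x": [p.x for p in nodes.values()],
            "y": [p.y for p in nodes.values()],
        }
    ).to_csv(nodes_path, index=False)
    rows = [
        (u, v, d["length"]) for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["from_id", "to_id", "length_m"]).to_csv(
        edges_path, index=False
    )


def read_schedule(path: str | Path, name: str | None = None) -> UtilizationSchedule:
    """Utilization schedule CSV: age_group, proportion."""
    df = pd.read_csv(path)
    _require_columns(df, ["age_group", "proportion"], path)
    coeffs = dict(zip(df["age_group"].astype(str), df["proportion"].astype(float)))
    return UtilizationSchedule(name or Path(path).stem, coeffs)


def write_scores_csv(scores: AccessibilityScores, path: str | Path) -> None:
    scores.to_frame().to_csv(path, index=False)


def write_scores_geojson(
    scores: AccessibilityScores, zones, path: str | Path
) -> None:
    """Join accessibility onto zone geometries (null where missing)."""
    by_id = dict(zip(scores.zone_ids, scores.values))
    props = {
        z.id: {
            "A": None if not np.isfinite(by_id.get(z.id, np.nan)) else float(by_id[z.id]),
            "method": scores.method,
            "d0_m": scores.d0,
        }
        for z in zones
    }
    write_zones(zones, path, properties=props)
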