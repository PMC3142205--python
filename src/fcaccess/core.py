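"""Geometry, travel distances, catchments and spatial weight matrices.

All coordinates are planar eastings/northings in meters (projected CRS).
Geographic longitude/latitude input is rejected: every distance threshold
in the accessibility workflow is metric.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import networkx as nx
from scipy import sparse
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon
from shapely.strtree import STRtree

__all__ = [
    "PointLocation",
    "Zone",
    "StreetNetwork",
    "DistanceMatrix",
    "SpatialWeightMatrix",
    "euclidean_distance_matrix",
    "shortest_path_distance_matrix",
    "catchment_members",
    "queen_contiguity",
    "inverse_distance_squared_weights",
]


@dataclasses.dataclass(frozen=True)
class PointLocation:
    """A point in a projected (planar, meters) coordinate system."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclasses.dataclass
class Zone:
    """A demand zone: identifier, centroid, optional boundary polygon.

    The centroid is whatever the data supplier provides (geometric or
    population-weighted); when a polygon is given and no centroid is
    supplied, the polygon's area centroid is used.
    """

    id: str
    centroid: PointLocation
    polygon: Polygon | None = None

    @classmethod
    def from_polygon(cls, id: str, polygon: Polygon) -> "Zone":
        if not polygon.is_valid:
            raise ValueError(f"zone {id!r}: invalid (self-intersecting?) polygon")
        c = polygon.centroid
        return cls(id=id, centroid=PointLocation(c.x, c.y), polygon=polygon)


class StreetNetwork:
    """An undirected street graph with metric edge lengths.

    Parameters
    ----------
    nodes : mapping of node id -> PointLocation
    edges : iterable of (node_id, node_id, length_m); lengths must be > 0.
    """

    def __init__(self, nodes: dict, edges: Sequence[tuple]) -> None:
        if not nodes:
            raise ValueError("empty network")
        g = nx.Graph()
        for nid, pt in nodes.items():
            g.add_node(nid, x=pt.x, y=pt.y)
        for u, v, length in edges:
            if length <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive length {length}")
            g.add_edge(u, v, length=float(length))
        self.graph = g
        self._node_ids = list(nodes)
        self._node_xy = np.array([[nodes[n].x, nodes[n].y] for n in self._node_ids])

    @property
    def nodes(self) -> dict:
        return {
            n: PointLocation(d["x"], d["y"]) for n, d in self.graph.nodes(data=True)
        }

    def snap(self, points: Sequence[PointLocation]) -> list:
        """Nearest-node snap; distance ties broken by lowest node id."""
        pts = np.array([[p.x, p.y] for p in points])
        d = cdist(pts, self._node_xy)
        snapped = []
        for row in d:
            best = np.flatnonzero(row == row.min())
            # lexicographically smallest id among equidistant nodes
            snapped.append(min((self._node_ids[i] for i in best), key=str))
        return snapped


@dataclasses.dataclass
class DistanceMatrix:
    """Demand-by-supply travel distances in meters.

    ``values[i, j]`` is the distance from ``origin_ids[i]`` to
    ``destination_ids[j]``; unreachable pairs hold ``np.inf`` and never
    enter any catchment.
    """

    origin_ids: list
    destination_ids: list
    values: np.ndarray
    metric: str  # "euclidean" | "network"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.origin_ids), len(self.destination_ids)):
            raise ValueError("distance matrix shape does not match id lists")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    def to_long_frame(self):
        import pandas as pd

        o, d = np.meshgrid(
            np.arange(len(self.origin_ids)),
            np.arange(len(self.destination_ids)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "origin_id": np.asarray(self.origin_ids, dtype=object)[o.ravel()],
                "destination_id": np.asarray(self.destination_ids, dtype=object)[
                    d.ravel()
                ],
                "meters": self.values.ravel(),
            }
        )


@dataclasses.dataclass
class SpatialWeightMatrix:
    """Zone-by-zone spatial weights with zero diagonal.

    kind is "queen" (binary adjacency) or "inverse_distance_squared"
    (w_ij = 1/d_ij^2, meters^-2). Weights are used raw by default; row
    standardization is an explicit transform.
    """

    ids: list
    w: sparse.csr_matrix
    kind: str

    def __post_init__(self) -> None:
        self.w = sparse.csr_matrix(self.w)
        n = len(self.ids)
        if self.w.shape != (n, n):
            raise ValueError("weight matrix shape does not match ids")
        if np.any(self.w.diagonal() != 0):
            raise ValueError("diagonal weights must be zero")

    def row_standardized(self) -> "SpatialWeightMatrix":
        rs = np.asarray(self.w.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        d = sparse.diags(1.0 / rs)
        return SpatialWeightMatrix(self.ids, d @ self.w, self.kind + "_row_std")

    @property
    def dense(self) -> np.ndarray:
        return self.w.toarray()


def _coords(points: Sequence[PointLocation]) -> np.ndarray:
    if len(points) == 0:
        raise ValueError("empty point sequence")
    arr = np.array([[p.x, p.y] for p in points], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinates")
    return arr


def euclidean_distance_matrix(
    origins: Sequence[PointLocation], destinations: Sequence[PointLocation]
) -> DistanceMatrix:
    """Straight-line distances in meters between two point sets."""
    o = _coords(origins)
    d = _coords(destinations)
    return DistanceMatrix(
        origin_ids=list(range(len(origins))),
        destination_ids=list(range(len(destinations))),
        values=cdist(o, d),
        metric="euclidean",
    )


def shortest_path_distance_matrix(
    network: StreetNetwork,
    origins: Sequence[PointLocation],
    destinations: Sequence[PointLocation],
    *,
    add_access_hops: bool = False,
) -> DistanceMatrix:
    """Shortest network-path distances between snapped points.

    Each point attaches to its nearest network node (ties to lowest node
    id). By default the point-to-node access hop is not added to the path
    length; set ``add_access_hops=True`` to add the Euclidean hop at both
    ends. Unreachable pairs get ``np.inf``.
    """
    o_nodes = network.snap(origins)
    d_nodes = network.snap(destinations)
    uniq_d = sorted(set(d_nodes), key=str)
    d_index = {n: k for k, n in enumerate(uniq_d)}
    n_o, n_d = len(origins), len(destinations)
    # one Dijkstra per unique origin node
    per_node = {}
    for src in set(o_nodes):
        lengths = nx.single_source_dijkstra_path_length(
            network.graph, src, weight="length"
        )
        per_node[src] = np.array(
            [lengths.get(t, np.inf) for t in uniq_d], dtype=float
        )
    vals = np.empty((n_o, n_d))
    for i, src in enumerate(o_nodes):
        row = per_node[src]
        vals[i] = row[[d_index[t] for t in d_nodes]]
    if add_access_hops:
        nodes = network.nodes
        o_hop = np.array(
            [math.hypot(p.x - nodes[n].x, p.y - nodes[n].y) for p, n in zip(origins, o_nodes)]
        )
        d_hop = np.array(
            [math.hypot(p.x - nodes[n].x, p.y - nodes[n].y) for p, n in zip(destinations, d_nodes)]
        )
        finite = np.isfinite(vals)
        vals = np.where(finite, vals + o_hop[:, None] + d_hop[None, :], vals)
    return DistanceMatrix(
        origin_ids=list(range(n_o)),
        destination_ids=list(range(n_d)),
        values=vals,
        metric="network",
    )


def catchment_members(dm: DistanceMatrix, d0: float) -> dict:
    """Closed-threshold catchment membership derived from one matrix.

    Returns ``{"by_destination": {dest_id: [origin ids with d <= d0]},
    "by_origin": {origin_id: [dest ids with d <= d0]}}``. The inequality is
    inclusive (d == d0 is a member) and both directions come from the same
    matrix, so catchments are symmetric.
    """
    if d0 <= 0:
        raise ValueError(f"threshold d0 must be positive, got {d0}")
    inside = dm.values <= d0
    by_dest = {
        dest: [dm.origin_ids[i] for i in np.flatnonzero(inside[:, j])]
        for j, dest in enumerate(dm.destination_ids)
    }
    by_origin = {
        orig: [dm.destination_ids[j] for j in np.flatnonzero(inside[i, :])]
        for i, orig in enumerate(dm.origin_ids)
    }
    return {"by_destination": by_dest, "by_origin": by_origin}


def queen_contiguity(
    zones: Sequence[Zone], *, tolerance: float = 0.0
) -> SpatialWeightMatrix:
    """Binary queen adjacency: 1 iff polygons share any boundary point.

    Corner-touching neighbours count (queen, not rook). ``tolerance``
    buffers each polygon before testing, for datasets with small gaps.
    """
    polys = []
    for z in zones:
        if z.polygon is None:
            raise ValueError(f"zone {z.id!r} has no polygon")
        if not z.polygon.is_valid:
            raise ValueError(f"zone {z.id!r}: invalid polygon")
        polys.append(z.polygon.buffer(tolerance) if tolerance > 0 else z.polygon)
    tree = STRtree(polys)
    rows, cols = [], []
    for i, p in enumerate(polys):
        for j in tree.query(p, predicate="intersects"):
            j = int(j)
            if j != i:
                rows.append(i)
                cols.append(j)
    n = len(polys)
    w = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    w.data[:] = 1.0  # collapse duplicate entries to binary
    return SpatialWeightMatrix([z.id for z in zones], w, "queen")


def inverse_distance_squared_weights(
    centroids: Sequence[PointLocation],
) -> SpatialWeightMatrix:
    """w_ij = 1 / d_ij^2 (meters^-2) between zone centroids, zero diagonal."""
    xy = _coords(centroids)
    d = cdist(xy, xy)
    off = ~np.eye(len(centroids), dtype=bool)
    if np.any(d[off] == 0):
        i, j = map(int, np.argwhere((d == 0) & off)[0])
        raise ValueError(f"coincident centroids at positions {i} and {j}")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off] ** 2
    return SpatialWeightMatrix(
        list(range(len(centroids))), sparse.csr_matrix(w), "inverse_distance_squared"
    )
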