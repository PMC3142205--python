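"""Spatial autocorrelation and centrography.

Moran's I in its classic (raw-weight) form with significance under the
normality assumption; weighted mean center; weighted standard deviational
ellipse; Clark-Evans nearest-neighbour index; point-in-polygon counts.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import numpy as np
from scipy import sparse, stats
from scipy.spatial import cKDTree, ConvexHull
from shapely.geometry import Point
from shapely.strtree import STRtree

from .core import PointLocation, SpatialWeightMatrix, Zone

__all__ = [
    "MoranResult",
    "morans_i",
    "weighted_mean_center",
    "StandardDeviationalEllipse",
    "standard_deviational_ellipse",
    "NearestNeighbourResult",
    "nearest_neighbour_index",
    "points_per_zone",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z: float
    p: float  # two-sided


def morans_i(
    y, w: SpatialWeightMatrix, *, variance: str = "normality"
) -> MoranResult:
    """Global Moran's I with raw (non-standardized) weights.

        I = (n / S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

    E[I] = -1/(n-1). The default variance is the closed form under the
    normality assumption; ``variance="randomization"`` uses the
    permutation-moment formula instead. z = (I - E[I]) / sqrt(var), p is
    two-sided normal.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 spatial units")
    if np.ptp(y) == 0:
        raise ValueError("constant attribute: Moran's I undefined")
    W = sparse.csr_matrix(w.w, dtype=float)
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("all-zero weight matrix")
    z_ = y - y.mean()
    num = float(z_ @ (W @ z_))
    den = float(z_ @ z_)
    I = (n / s0) * num / den

    e_i = -1.0 / (n - 1)
    Wt = W.T.tocsr()
    s1 = float(((W + Wt).power(2)).sum()) / 2.0
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    s2 = float(np.sum((row + col) ** 2))
    if variance == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (
            (n * n - 1) * s0 * s0
        ) - e_i * e_i
    elif variance == "randomization":
        b2 = n * np.sum(z_**4) / (np.sum(z_**2) ** 2)
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    else:
        raise ValueError(f"unknown variance scheme {variance!r}")
    if var <= 0:
        raise ValueError("non-positive Moran variance (degenerate weights)")
    zscore = (I - e_i) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=I, expected_I=e_i, variance=var, z=zscore, p=p)


def weighted_mean_center(
    points: Sequence[PointLocation], weights=None
) -> PointLocation:
    """(sum w x / sum w, sum w y / sum w); equal weights -> plain centroid."""
    xy = np.array([[p.x, p.y] for p in points], dtype=float)
    w = np.ones(len(points)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weights sum to zero")
    cx, cy = (w @ xy) / tot
    return PointLocation(cx, cy)


@dataclasses.dataclass
class StandardDeviationalEllipse:
    center: PointLocation
    sigma_x: float  # major semi-axis, meters
    sigma_y: float  # minor semi-axis, meters (sigma_y <= sigma_x)
    rotation_deg: float  # major-axis angle from the +x (east) axis, in [0, 180)


def standard_deviational_ellipse(
    points: Sequence[PointLocation], weights=None
) -> StandardDeviationalEllipse:
    """Weighted standard deviational ellipse (dof-uncorrected moments).

    The rotation comes from the standard arctangent expression on
    coordinates centered at the weighted mean center; the semi-axes are
    root weighted second moments along the rotated axes. Degenerate
    (collinear) point sets are reported with a zero minor axis and a
    warning, not an error.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    xy = np.array([[p.x, p.y] for p in points], dtype=float)
    w = np.ones(len(points)) if weights is None else np.asarray(weights, dtype=float)
    center = weighted_mean_center(points, w)
    dx = xy[:, 0] - center.x
    dy = xy[:, 1] - center.y
    sxx = float(np.sum(w * dx * dx))
    syy = float(np.sum(w * dy * dy))
    sxy = float(np.sum(w * dx * dy))
    if sxx == 0 and syy == 0:
        raise ValueError("all points coincide: ellipse undefined")
    if sxy == 0:
        theta = 0.0 if sxx >= syy else math.pi / 2
    else:
        diff = sxx - syy
        theta = math.atan((diff + math.sqrt(diff * diff + 4 * sxy * sxy)) / (2 * sxy))
    c, s = math.cos(theta), math.sin(theta)
    tot = float(w.sum())
    sig_x = math.sqrt(max(0.0, np.sum(w * (dx * c - dy * s) ** 2) / tot))
    sig_y = math.sqrt(max(0.0, np.sum(w * (dx * s + dy * c) ** 2) / tot))
    if sig_x < sig_y:  # report the major axis as x' (angle from east)
        sig_x, sig_y = sig_y, sig_x
        theta += math.pi / 2
    if min(sig_x, sig_y) == 0:
        log.warning("collinear point configuration: degenerate ellipse")
    return StandardDeviationalEllipse(
        center=center,
        sigma_x=sig_x,
        sigma_y=sig_y,
        rotation_deg=math.degrees(theta) % 180.0,
    )


@dataclasses.dataclass
class NearestNeighbourResult:
    observed_mean_distance: float  # meters
    expected_mean_distance: float  # 0.5 * sqrt(A / n), meters
    index: float  # observed / expected; < 1 means clustering
    z: float
    p: float  # two-sided


def nearest_neighbour_index(
    points: Sequence[PointLocation],
    area: float | None = None,
) -> NearestNeighbourResult:
    """Clark-Evans nearest-neighbour index against complete randomness.

    ``area`` is the study-region area in m^2 — a modelling choice, so it
    must normally be supplied; if omitted, the convex-hull area is used
    with a warning. SE of the expected mean distance is
    0.26136 / sqrt(n^2 / A). Coincident points contribute distance 0 and
    are retained (with a warning).
    """
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    xy = np.array([[p.x, p.y] for p in points], dtype=float)
    if area is None:
        area = float(ConvexHull(xy).volume)
        log.warning(
            "no study area supplied; using convex hull area %.1f m^2 "
            "(this understates dispersion near hull edges)",
            area,
        )
    if area <= 0:
        raise ValueError("area must be positive")
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    nn = d[:, 1]
    if np.any(nn == 0):
        log.warning("coincident points present: zero nearest-neighbour distances kept")
    d_obs = float(nn.mean())
    d_exp = 0.5 * math.sqrt(area / n)
    se = 0.26136 / math.sqrt(n * n / area)
    z = (d_obs - d_exp) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return NearestNeighbourResult(
        observed_mean_distance=d_obs,
        expected_mean_distance=d_exp,
        index=d_obs / d_exp,
        z=z,
        p=p,
    )


def points_per_zone(
    points: Sequence[PointLocation], zones: Sequence[Zone]
) -> tuple[dict, int]:
    """Count points per zone polygon (boundary-inclusive, counted once).

    A point on a shared boundary is assigned to the first zone (input
    order) whose polygon covers it. Returns (counts by zone id,
    unassigned count); totals are preserved.
    """
    polys = []
    for z in zones:
        if z.polygon is None:
            raise ValueError(f"zone {z.id!r} has no polygon")
        polys.append(z.polygon)
    tree = STRtree(polys)
    counts = {z.id: 0 for z in zones}
    unassigned = 0
    for p in points:
        hits = sorted(int(j) for j in tree.query(Point(p.x, p.y), predicate="covered_by"))
        if hits:
            counts[zones[hits[0]].id] += 1
        else:
            unassigned += 1
    return counts, unassigned
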