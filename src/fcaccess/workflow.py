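"""End-to-end report: both methods at every threshold, plus comparisons.

``run_report`` reproduces the full analysis layout on any instance:
demand summary, per-method/threshold accessibility summaries, Spearman
rank correlations between methods, difference-score tables, Moran's I of
the differences under queen and inverse-distance-squared weights, clinic
centrography, and GeoJSON difference layers. Outputs are plain CSV/JSON
and byte-stable for a fixed input and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, spatial_stats
from .core import (
    DistanceMatrix,
    euclidean_distance_matrix,
    inverse_distance_squared_weights,
    queen_contiguity,
    shortest_path_distance_matrix,
)
from .demand import load_default_schedules, summarize_demand
from .engine import run_2sfca, summarize_scores
from .io import RunConfig, write_scores_csv, write_scores_geojson, write_zones

log = logging.getLogger(__name__)

__all__ = ["compute_distances", "run_report"]


def compute_distances(demand, supply, *, metric="euclidean", network=None) -> DistanceMatrix:
    """Demand-by-supply distances with real zone/clinic ids attached."""
    origins = [u.zone.centroid for u in demand]
    destinations = [s.location for s in supply]
    if metric == "euclidean":
        dm = euclidean_distance_matrix(origins, destinations)
    elif metric == "network":
        if network is None:
            raise ValueError("network metric requested but no network supplied")
        dm = shortest_path_distance_matrix(network, origins, destinations)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    dm.origin_ids = [u.id for u in demand]
    dm.destination_ids = [s.id for s in supply]
    return dm


def run_report(
    supply,
    demand,
    zones=None,
    network=None,
    *,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run both methods at all thresholds; write tables and layers.

    Returns a dict of the in-memory results; when ``out_dir`` is given the
    same content is written as CSV/GeoJSON plus a machine-readable
    ``run_log.json`` recording the per-stage bookkeeping (clinics with
    empty catchments, zones without access).
    """
    cfg = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if any(u.W_k is None for u in demand):
        schedule = load_default_schedules()[cfg.schedule]
        demand = [u.with_potential_users(schedule) for u in demand]

    dm = compute_distances(demand, supply, metric=cfg.metric, network=network)

    results: dict = {
        "demand_summary": summarize_demand(demand),
        "scores": {},
        "score_summaries": {},
        "spearman": {},
        "differences": {},
        "difference_tables": {},
        "moran": {},
        "run_log": {
            "metric": cfg.metric,
            "thresholds_m": list(cfg.thresholds),
            "methods": list(cfg.methods),
            "schedule": cfg.schedule,
            "seed": cfg.seed,
            "n_supply": len(supply),
            "n_demand": len(demand),
            "stages": [],
        },
    }

    w_queen = w_idw = None
    if zones is not None and all(z.polygon is not None for z in zones):
        w_queen = queen_contiguity(zones)
    if zones is not None:
        w_idw = inverse_distance_squared_weights([z.centroid for z in zones])

    for d0 in cfg.thresholds:
        for method in cfg.methods:
            sc = run_2sfca(supply, demand, dm, d0, method)
            results["scores"][(method, d0)] = sc
            results["score_summaries"][(method, d0)] = summarize_scores(sc)
            results["run_log"]["stages"].append(
                {
                    "method": method,
                    "d0_m": d0,
                    "zones_with_access": sc.n_defined,
                    "zones_without_access": len(demand) - sc.n_defined,
                }
            )
            if out is not None:
                write_scores_csv(sc, out / f"scores_{method}_{int(d0)}m.csv")
        if {"conventional", "optimized"} <= set(cfg.methods):
            conv = results["scores"][("conventional", d0)]
            opt = results["scores"][("optimized", d0)]
            both = conv.defined & opt.defined
            if both.sum() >= 3 and np.ptp(conv.values[both]) > 0 and np.ptp(opt.values[both]) > 0:
                rho, p = compare.spearman_rho(conv.values[both], opt.values[both])
                results["spearman"][d0] = {"rho": rho, "p": p, "n": int(both.sum())}
                diff = compare.difference_scores(conv, opt)
                results["differences"][d0] = diff
                results["difference_tables"][d0] = compare.difference_percentile_table(
                    diff.D
                )
                if zones is not None:
                    results["moran"][d0] = _moran_of_differences(
                        diff, zones, w_queen, w_idw
                    )
                if out is not None:
                    diff.to_frame().to_csv(
                        out / f"differences_{int(d0)}m.csv", index=False
                    )
                    if zones is not None:
                        d_by_id = dict(zip(diff.zone_ids, diff.D))
                        write_zones(
                            zones,
                            out / f"differences_{int(d0)}m.geojson",
                            properties={
                                z.id: {
                                    "D": (
                                        float(d_by_id[z.id])
                                        if z.id in d_by_id
                                        else None
                                    ),
                                    "d0_m": d0,
                                }
                                for z in zones
                            },
                        )

    clinic_pts = [s.location for s in supply]
    phys = [s.P_j for s in supply]
    cent = {
        "mean_center": spatial_stats.weighted_mean_center(clinic_pts, phys),
    }
    if len(clinic_pts) >= 3:
        cent["sde"] = spatial_stats.standard_deviational_ellipse(clinic_pts, phys)
    if len(clinic_pts) >= 2 and zones is not None:
        area = sum(z.polygon.area for z in zones if z.polygon is not None)
        if area > 0:
            cent["nni"] = spatial_stats.nearest_neighbour_index(clinic_pts, area)
    results["centrography"] = cent

    if out is not None:
        _write_tables(results, out, cfg)
    return results


def _moran_of_differences(diff, zones, w_queen, w_idw) -> dict:
    """Moran's I of D on the zones where D is defined (weights subset)."""
    idx = {z.id: i for i, z in enumerate(zones)}
    keep = np.array([idx[z] for z in diff.zone_ids if z in idx])
    d = np.array([v for z, v in zip(diff.zone_ids, diff.D) if z in idx])
    out = {}
    for name, w in (("queen", w_queen), ("inverse_distance_squared", w_idw)):
        if w is None or keep.size < 3 or np.ptp(d) == 0:
            continue
        sub = w.w[np.ix_(keep, keep)]
        if sub.sum() == 0:
            continue
        from .core import SpatialWeightMatrix

        res = spatial_stats.morans_i(
            d, SpatialWeightMatrix(list(diff.zone_ids), sub, w.kind)
        )
        out[name] = res
    return out


def _write_tables(results: dict, out: Path, cfg: RunConfig) -> None:
    results["demand_summary"].to_csv(out / "demand_summary.csv")
    rows = []
    for (method, d0), s in sorted(results["score_summaries"].items()):
        row = {"method": method, "d0_m": d0, "metric": cfg.metric}
        row.update(s.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "score_summaries.csv", index=False)

    if results["spearman"]:
        pd.DataFrame(
            [
                {"d0_m": d0, **vals}
                for d0, vals in sorted(results["spearman"].items())
            ]
        ).to_csv(out / "spearman.csv", index=False)
    if results["difference_tables"]:
        rows = []
        for d0, s in sorted(results["difference_tables"].items()):
            row = {"d0_m": d0}
            row.update(s.to_dict())
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "difference_tables.csv", index=False)
    if results["moran"]:
        rows = []
        for d0, by_w in sorted(results["moran"].items()):
            for wname, r in sorted(by_w.items()):
                rows.append(
                    {
                        "d0_m": d0,
                        "weights": wname,
                        "morans_I": r.I,
                        "expected_I": r.expected_I,
                        "z": r.z,
                        "p": r.p,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "moran.csv", index=False)

    cent = results.get("centrography", {})
    cent_json: dict = {}
    if "mean_center" in cent:
        mc = cent["mean_center"]
        cent_json["mean_center"] = {"x": mc.x, "y": mc.y}
    if "sde" in cent:
        e = cent["sde"]
        cent_json["standard_deviational_ellipse"] = {
            "center_x": e.center.x,
            "center_y": e.center.y,
            "sigma_x_m": e.sigma_x,
            "sigma_y_m": e.sigma_y,
            "rotation_deg": e.rotation_deg,
        }
    if "nni" in cent:
        n = cent["nni"]
        cent_json["nearest_neighbour"] = {
            "observed_mean_m": n.observed_mean_distance,
            "expected_mean_m": n.expected_mean_distance,
            "index": n.index,
            "z": n.z,
            "p": n.p,
        }
    with open(out / "centrography.json", "w") as fh:
        json.dump(cent_json, fh, sort_keys=True, indent=2)
        fh.write("\n")
    with open(out / "run_log.json", "w") as fh:
        json.dump(results["run_log"], fh, sort_keys=True, indent=2)
        fh.write("\n")
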