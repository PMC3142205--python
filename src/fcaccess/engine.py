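"""The two-step floating catchment area (2SFCA) computation.

Step 1: each supply site j gets a supply-to-demand ratio over the demand
within its catchment (closed threshold d <= d0), scaled per 1,000 persons:

    conventional  R_j = 1000 * S_j / sum_{k: d_kj <= d0} D_k
    optimized     R_j = 1000 * P_j / sum_{k: d_kj <= d0} W_k

Step 2: each demand unit i sums the ratios of the supply sites within its
own catchment: A_i = sum_{j: d_ij <= d0} R_j.

Sites whose catchment holds no demand get an undefined ratio and
contribute nothing at step 2; demand units with no site in range get a
missing score (NaN), not zero — the count of defined scores is the N the
summaries report. A_i is in supply units (clinics or physicians) per
1,000 persons.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import DistanceMatrix, PointLocation
from .demand import DemandUnit, describe

__all__ = [
    "SupplySite",
    "SupplyRatios",
    "AccessibilityScores",
    "step1_supply_ratios",
    "step2_accessibility",
    "run_2sfca",
    "summarize_scores",
]

log = logging.getLogger(__name__)

METHODS = ("conventional", "optimized")


@dataclasses.dataclass
class SupplySite:
    """One clinic: location, unit capacity S_j, physician count P_j."""

    id: str
    location: PointLocation
    S_j: float = 1.0
    P_j: int = 1

    def __post_init__(self) -> None:
        if self.S_j <= 0:
            raise ValueError(f"site {self.id!r}: capacity S_j must be > 0")
        if self.P_j < 1:
            raise ValueError(f"site {self.id!r}: physician count P_j must be >= 1")


@dataclasses.dataclass
class SupplyRatios:
    """Per-site ratios R_j (supply units per 1,000 persons); NaN = undefined."""

    site_ids: list
    values: np.ndarray
    d0: float
    method: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclasses.dataclass
class AccessibilityScores:
    """Per-zone accessibility A_i; NaN marks zones with no site in range."""

    zone_ids: list
    values: np.ndarray
    d0: float
    method: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone_id": self.zone_ids,
                "method": self.method,
                "d0_m": self.d0,
                "A": self.values,
                "defined": self.defined,
            }
        )


def _check(dm: DistanceMatrix, supply: Sequence[SupplySite], demand: Sequence[DemandUnit], d0: float, method: str) -> None:
    if d0 <= 0:
        raise ValueError(f"threshold d0 must be positive, got {d0}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(dm.origin_ids) != len(demand) or len(dm.destination_ids) != len(supply):
        raise ValueError(
            "distance matrix must be demand-by-supply: "
            f"got {dm.values.shape}, expected ({len(demand)}, {len(supply)})"
        )


def step1_supply_ratios(
    supply: Sequence[SupplySite],
    demand: Sequence[DemandUnit],
    dm: DistanceMatrix,
    d0: float,
    method: str = "conventional",
) -> SupplyRatios:
    """Supply-to-demand ratios per 1,000 within each site's catchment."""
    _check(dm, supply, demand, d0, method)
    inside = dm.values <= d0  # demand x supply
    if method == "conventional":
        numer = np.array([s.S_j for s in supply], dtype=float)
        dem = np.array([u.D_k for u in demand], dtype=float)
    else:
        numer = np.array([s.P_j for s in supply], dtype=float)
        if any(u.W_k is None for u in demand):
            raise ValueError("optimized method needs W_k; apply a utilization schedule")
        dem = np.array([u.W_k for u in demand], dtype=float)
    denom = dem @ inside  # per-site demand within d0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, 1000.0 * numer / denom, np.nan)
    n_empty = int(np.sum(denom <= 0))
    if n_empty:
        log.warning(
            "%d of %d supply sites have empty catchments at d0=%g m; "
            "their ratios are undefined",
            n_empty,
            len(supply),
            d0,
        )
    return SupplyRatios([s.id for s in supply], r, d0, method)


def step2_accessibility(
    ratios: SupplyRatios,
    demand: Sequence[DemandUnit],
    dm: DistanceMatrix,
    d0: float | None = None,
    *,
    allow_threshold_mismatch: bool = False,
) -> AccessibilityScores:
    """Sum reachable sites' ratios per demand unit; no site in range -> NaN."""
    if d0 is None:
        d0 = ratios.d0
    if d0 != ratios.d0 and not allow_threshold_mismatch:
        raise ValueError(
            f"step-2 threshold {d0} differs from step-1 threshold {ratios.d0}; "
            "pass allow_threshold_mismatch=True to run anyway"
        )
    inside = dm.values <= d0  # demand x supply
    r = np.where(np.isfinite(ratios.values), ratios.values, 0.0)
    a = inside @ r
    has_site = inside.any(axis=1)
    a = np.where(has_site, a, np.nan)
    n_missing = int(np.sum(~has_site))
    if n_missing:
        log.info(
            "%d of %d demand units have no supply within d0=%g m",
            n_missing,
            len(demand),
            d0,
        )
    return AccessibilityScores([u.id for u in demand], a, d0, ratios.method)


def run_2sfca(
    supply: Sequence[SupplySite],
    demand: Sequence[DemandUnit],
    dm: DistanceMatrix,
    d0: float,
    method: str = "conventional",
) -> AccessibilityScores:
    """Both steps at a single threshold; deterministic."""
    ratios = step1_supply_ratios(supply, demand, dm, d0, method)
    return step2_accessibility(ratios, demand, dm)


def summarize_scores(scores: AccessibilityScores) -> pd.Series:
    """Descriptive statistics over defined scores only (N counts them)."""
    if not np.any(scores.defined):
        raise ValueError("all scores missing: no demand unit has supply in range")
    return describe(scores.values[scores.defined])
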