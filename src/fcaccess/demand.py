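"""Age-weighted demand: convert zone age structures into potential users.

The demand side of the optimized accessibility method replaces raw zone
population D_k with potential users W_k = sum_x c_x * P_x, where P_x is the
population in ten-year age bin x and c_x is the proportion of that age
group that visited a medical clinic in the past year. Default c_x
schedules (Montreal, Quebec, Canada; 2005-2006 community health survey
estimates) ship with the package.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from importlib import resources

import numpy as np
import pandas as pd

from .core import Zone

__all__ = [
    "AGE_BINS",
    "UtilizationSchedule",
    "DemandUnit",
    "potential_users",
    "load_default_schedules",
    "summarize_demand",
    "describe",
]

#: The nine ten-year age bins, ordered, non-overlapping, exhaustive.
AGE_BINS: tuple[str, ...] = (
    "0-14",
    "15-19",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80+",
)


@dataclasses.dataclass(frozen=True)
class UtilizationSchedule:
    """Past-year clinic-utilization proportion c_x per age bin."""

    name: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [b for b in AGE_BINS if b not in self.coefficients]
        if missing:
            raise ValueError(f"schedule {self.name!r} missing bins {missing}")
        for b in AGE_BINS:
            c = self.coefficients[b]
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coefficient for {b} out of [0, 1]: {c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.coefficients[b] for b in AGE_BINS], dtype=float)

    def __getitem__(self, age_bin: str) -> float:
        return self.coefficients[age_bin]


IDENTITY_SCHEDULE = UtilizationSchedule("identity", {b: 1.0 for b in AGE_BINS})


@dataclasses.dataclass
class DemandUnit:
    """One demand zone with its age-structured population.

    D_k is the total population; W_k the potential clinic users implied by
    the utilization schedule. W_k is kept fractional.
    """

    zone: Zone
    age_counts: Mapping[str, float]
    W_k: float | None = None

    def __post_init__(self) -> None:
        for b in AGE_BINS:
            if self.age_counts.get(b, 0) < 0:
                raise ValueError(
                    f"zone {self.zone.id!r}: negative count in bin {b}"
                )

    @property
    def id(self) -> str:
        return self.zone.id

    @property
    def D_k(self) -> float:
        return float(sum(self.age_counts.get(b, 0.0) for b in AGE_BINS))

    def with_potential_users(self, schedule: UtilizationSchedule) -> "DemandUnit":
        return dataclasses.replace(
            self, W_k=potential_users(self.age_counts, schedule)
        )


def potential_users(
    age_counts: Mapping[str, float], schedule: UtilizationSchedule
) -> float:
    """W_k = sum over age bins of c_x * P_x (persons, fractional)."""
    total = 0.0
    for b in AGE_BINS:
        p = age_counts.get(b, 0.0)
        if p < 0:
            raise ValueError(f"negative count in bin {b}: {p}")
        total += schedule[b] * p
    return total


def load_default_schedules() -> dict[str, UtilizationSchedule]:
    """The packaged Montreal / Quebec / Canada utilization schedules."""
    with resources.files("fcaccess.data").joinpath(
        "utilization_schedules.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("age_group")
    return {
        name: UtilizationSchedule(name, df[name].to_dict())
        for name in ("montreal", "quebec", "canada")
    }


_PCTS = (5, 25, 50, 75, 95)


def describe(values: Sequence[float], percentiles=_PCTS) -> pd.Series:
    """N / mean / SD / min / max / percentiles with linear interpolation.

    SD is the sample standard deviation (ddof=1); a single value gives
    SD 0. Percentiles interpolate linearly between order statistics.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined values to summarize")
    out = {
        "N": v.size,
        "mean": v.mean(),
        "std": v.std(ddof=1) if v.size > 1 else 0.0,
        "min": v.min(),
        "max": v.max(),
    }
    for p in percentiles:
        out[f"p{p}"] = np.percentile(v, p, method="linear")
    return pd.Series(out)


def summarize_demand(units: Sequence[DemandUnit]) -> pd.DataFrame:
    """Descriptive statistics of population D and potential users W."""
    if len(units) == 0:
        raise ValueError("no demand units")
    d = [u.D_k for u in units]
    if any(u.W_k is None for u in units):
        raise ValueError("potential users W_k not computed; apply a schedule first")
    w = [u.W_k for u in units]
    return pd.DataFrame(
        {"total_population": describe(d), "potential_users": describe(w)}
    )
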