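"""Comparing conventional and optimized accessibility surfaces.

Both score sets are rescaled to 0-100 (min-max within the zones where both
are defined) and differenced: D = rescaled_conventional - rescaled_optimized.
Negative D means the conventional method under-estimates accessibility
relative to the optimized one. Rank agreement is measured with Spearman's
rho; the mean difference is tested against zero with a one-sample t-test
(default) or a Welch two-sample test of the rescaled scores.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .engine import AccessibilityScores

__all__ = [
    "DifferenceScores",
    "rescale_0_100",
    "difference_scores",
    "spearman_rho",
    "t_test_differences",
    "difference_percentile_table",
]


@dataclasses.dataclass
class DifferenceScores:
    """Per-zone rescaled scores and their difference D, one threshold."""

    zone_ids: list
    rescaled_conventional: np.ndarray
    rescaled_optimized: np.ndarray
    d0: float

    @property
    def D(self) -> np.ndarray:
        return self.rescaled_conventional - self.rescaled_optimized

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone_id": self.zone_ids,
                "d0_m": self.d0,
                "resc_conv": self.rescaled_conventional,
                "resc_opt": self.rescaled_optimized,
                "D": self.D,
            }
        )


def rescale_0_100(scores) -> np.ndarray:
    """Min-max rescale to [0, 100]: x -> 100 * (x - min) / (max - min)."""
    v = np.asarray(scores, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rescale")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("zero range: all values equal, rescaling undefined")
    return 100.0 * (v - lo) / (hi - lo)


def difference_scores(
    conv: AccessibilityScores, opt: AccessibilityScores
) -> DifferenceScores:
    """D on the zones where both methods are defined; rescaling within them."""
    if conv.d0 != opt.d0:
        raise ValueError(
            f"threshold mismatch: conventional at {conv.d0} m, optimized at {opt.d0} m"
        )
    if conv.zone_ids != opt.zone_ids:
        raise ValueError("score sets cover different zones")
    both = conv.defined & opt.defined
    ids = [z for z, b in zip(conv.zone_ids, both) if b]
    return DifferenceScores(
        zone_ids=ids,
        rescaled_conventional=rescale_0_100(conv.values[both]),
        rescaled_optimized=rescale_0_100(opt.values[both]),
        d0=conv.d0,
    )


def spearman_rho(a, b) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t approximation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def t_test_differences(
    D=None,
    *,
    mode: str = "one_sample",
    conv=None,
    opt=None,
) -> tuple[float, float, float]:
    """(t, p, mean_D). one_sample tests mean(D)=0; two_sample is Welch.

    Zero-variance D with n > 1 and nonzero mean yields t = +/-inf, p = 0.
    """
    if mode == "one_sample":
        d = np.asarray(D, dtype=float)
        if d.size < 2:
            raise ValueError("need n >= 2")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite differences")
        mean_d = float(d.mean())
        if d.std(ddof=1) == 0:
            if mean_d == 0:
                return 0.0, 1.0, 0.0
            return float(np.sign(mean_d)) * np.inf, 0.0, mean_d
        t, p = stats.ttest_1samp(d, 0.0)
        return float(t), float(p), mean_d
    if mode == "two_sample":
        a = np.asarray(conv, dtype=float)
        b = np.asarray(opt, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 in both samples")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p), float(a.mean() - b.mean())
    raise ValueError(f"unknown mode {mode!r}")


_PCTS = (5, 10, 25, 50, 75, 90, 95)


def difference_percentile_table(D) -> pd.Series:
    """Mean, one-sample p, and percentiles 5/10/25/50/75/90/95 of D."""
    d = np.asarray(D, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    out = {"mean": float(d.mean())}
    if d.size >= 2:
        _, p, _ = t_test_differences(d, mode="one_sample")
        out["p_value"] = p
    else:
        out["p_value"] = np.nan
    for p_ in _PCTS:
        out[f"p{p_}"] = float(np.percentile(d, p_, method="linear"))
    return pd.Series(out)
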