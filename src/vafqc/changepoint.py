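"""Two-part linear regression on cumulative curves.

A cumulative positivity curve typically shows a steep low-VAF portion (where
dilution by non-neoplastic DNA depresses positivity) and a shallow high-VAF
plateau. The changepoint is found by exhaustive search: every distinct curve
VAF with enough points on both sides is tried as a split, ordinary least
squares is fitted to each segment, and the split maximizing the signed slope
difference (low-segment slope minus high-segment slope) wins. Ties break
toward the smallest split.

The split point itself lies on both segments (low = VAF <= split, high =
VAF >= split), the usual two-phase-regression convention: the knee is the
last point of the rising limb and the first point of the plateau, so a
noiseless hinge is recovered exactly at its knee rather than one grid step
below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import CumulativeCurve
from .purity import RegressionResult, fit_line

__all__ = ["ChangepointFit", "two_part_fit", "enumerate_splits", "default_min_seg"]

# Adaptive floor on points per segment. Slope estimates over a handful of
# closely spaced points are noise-dominated (slope noise scales as
# sd / (x-spread * sqrt(k))), so the exhaustive slope-difference criterion
# would otherwise latch onto tiny end segments; 15% of the curve keeps each
# segment's slope informative while leaving the search effectively exhaustive.
_MIN_SEG_FRACTION = 0.15


def default_min_seg(n_points: int) -> int:
    """Default minimum points per segment: max(3, 15% of the curve)."""
    return max(3, round(_MIN_SEG_FRACTION * n_points))


@dataclass
class ChangepointFit:
    split_vaf: float
    low_fit: RegressionResult
    high_fit: RegressionResult
    slope_difference: float
    candidates_evaluated: int


def enumerate_splits(
    curve: CumulativeCurve, min_seg: int | None = None
) -> pd.DataFrame:
    """Per-candidate table backing :func:`two_part_fit`.

    One row per admissible split: the split VAF, both segment fits, and the
    signed slope difference. Candidates whose low or high segment has all-
    identical VAFs (undefined slope) are skipped. ``min_seg=None`` uses the
    adaptive default :func:`default_min_seg`.
    """
    x = curve.vaf_ranked
    y = curve.cumulative_value
    if min_seg is None:
        min_seg = default_min_seg(x.size)
    # the split point counts toward both segments
    if x.size < 2 * min_seg - 1:
        raise ValueError(
            f"curve needs at least {2 * min_seg - 1} points for "
            f"min_seg={min_seg}, got {x.size}"
        )
    rows = []
    for split in np.unique(x):
        low = x <= split
        high = x >= split  # split point shared by both segments
        if low.sum() < min_seg or high.sum() < min_seg:
            continue
        if np.ptp(x[low]) == 0.0 or np.ptp(x[high]) == 0.0:
            continue
        low_fit = fit_line(x[low], y[low])
        high_fit = fit_line(x[high], y[high])
        rows.append(
            {
                "split_vaf": float(split),
                "n_low": int(low.sum()),
                "n_high": int(high.sum()),
                "low_slope": low_fit.slope,
                "high_slope": high_fit.slope,
                "low_r_squared": low_fit.r_squared,
                "high_r_squared": high_fit.r_squared,
                "slope_difference": low_fit.slope - high_fit.slope,
            }
        )
    if not rows:
        raise ValueError("no admissible split with min_seg points per segment")
    return pd.DataFrame(rows)


def two_part_fit(
    curve: CumulativeCurve, min_seg: int | None = None
) -> ChangepointFit:
    """Exhaustive two-segment OLS changepoint fit of a cumulative curve.

    Returns the split maximizing the signed slope difference (low minus
    high); ties break toward the smallest split VAF. ``min_seg=None`` uses
    the adaptive default :func:`default_min_seg`.
    """
    table = enumerate_splits(curve, min_seg=min_seg)
    diffs = table["slope_difference"].to_numpy()
    # ties (within float jitter of the maximum) break toward the smallest split
    tol = 1e-9 * max(1.0, abs(float(diffs.max())))
    best = int(np.argmax(diffs >= diffs.max() - tol))
    split = float(table.iloc[best]["split_vaf"])
    x = curve.vaf_ranked
    y = curve.cumulative_value
    low_fit = fit_line(x[x <= split], y[x <= split])
    high_fit = fit_line(x[x >= split], y[x >= split])
    return ChangepointFit(
        split_vaf=split,
        low_fit=low_fit,
        high_fit=high_fit,
        slope_difference=low_fit.slope - high_fit.slope,
        candidates_evaluated=len(table),
    )
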