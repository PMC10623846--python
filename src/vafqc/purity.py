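"""Tumor cellularity from driver-mutation VAF, and comparison with microscopy.

Driver mutations of adult-type diffuse gliomas (TERT promoter in IDH-wildtype
GBM, IDH1/2 in the IDH-mutant subtypes) are nearly always heterozygous and
copy-number neutral, so tumor cellularity is estimated as 2 x VAF x 100%,
capped at 100% for the rare VAF > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "RegressionResult",
    "cellularity_from_vaf",
    "fit_line",
    "cellularity_discrepancy",
]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit summary: slope, intercept, R^2, and the
    two-sided p-value for slope deviation from zero (t distribution,
    n - 2 degrees of freedom)."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def cellularity_from_vaf(vaf: float) -> float:
    """Percent tumor cellularity = min(2 * VAF * 100, 100)."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    return min(2.0 * vaf * 100.0, 100.0)


def fit_line(x, y) -> RegressionResult:
    """Simple linear regression of y on x.

    Degenerate cases: all-identical x raises; constant y returns slope 0,
    R^2 0, p 1 (no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("all x values identical: slope undefined")
    if np.ptp(y) == 0.0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, n)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_slope=float(res.pvalue),
        n=n,
    )


def cellularity_discrepancy(
    samples: CohortTable,
) -> tuple[pd.DataFrame, RegressionResult]:
    """Microscopy-minus-VAF cellularity differences, regressed on VAF.

    For every sample carrying a microscopic cellularity estimate, the
    difference (in percentage points) between the microscopic estimate and
    the VAF-derived estimate is computed and regressed on VAF. A negative
    slope indicates that microscopy overestimates cellularity at low purity.
    """
    rows = []
    for s in samples:
        if s.micro_cellularity is None:
            continue
        est = cellularity_from_vaf(s.driver_vaf)
        rows.append(
            {
                "sample_id": s.sample_id,
                "driver_vaf": s.driver_vaf,
                "micro_cellularity": s.micro_cellularity,
                "vaf_cellularity": est,
                "difference": s.micro_cellularity - est,
            }
        )
    if len(rows) < 2:
        raise ValueError(
            "need at least 2 samples with micro_cellularity, got "
            f"{len(rows)}"
        )
    frame = pd.DataFrame(rows)
    fit = fit_line(frame["driver_vaf"].to_numpy(), frame["difference"].to_numpy())
    return frame, fit
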