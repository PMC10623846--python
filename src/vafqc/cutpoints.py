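"""Exhaustive Fisher-exact VAF cutpoint scanning and two-group comparisons.

The scan dichotomizes a cohort at every midpoint between consecutive distinct
VAFs, builds the 2x2 table (at/above vs below cutoff, positive vs negative
MGMT call), and reports the cutpoint minimizing the two-sided Fisher-exact
p-value. No multiple-testing correction is applied across candidates — the
minimal p-value is an optimized statistic and is reported raw; treat it as
descriptive, not as a calibrated significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Call, CohortTable

__all__ = ["Fisher2x2", "CutoffScanResult", "fisher_exact", "scan_vaf_cutoffs", "compare_groups"]


@dataclass(frozen=True)
class Fisher2x2:
    """2x2 contingency table; rows = at/above vs below a cutoff (or assay A
    vs assay B), columns = positive vs negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be nonnegative integers, got {self!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(table: Fisher2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``: the conditional sample odds ratio
    a*d / (b*c) (infinite when b*c = 0 and a*d > 0, NaN when both products
    vanish) and the two-sided p-value by the probability-mass-summation
    convention — the sum of hypergeometric probabilities, at fixed margins,
    of all tables no more probable than the observed one.
    """
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds_ratio = math.inf if ad > 0 else math.nan
    else:
        odds_ratio = ad / bc
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return odds_ratio, float(p)


@dataclass
class CutoffScanResult:
    """All candidate VAF cutpoints with their Fisher statistics, plus the
    optimal (minimal-p) cutpoint. ``degenerate`` marks cohorts whose calls
    are all identical, where no cutpoint can separate outcomes."""

    candidates: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    group_sizes: list[tuple[int, int]]
    optimal_cutoff: float
    optimal_p: float
    degenerate: bool = False
    min_per_side: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.candidates,
                "n_above": [g[0] for g in self.group_sizes],
                "n_below": [g[1] for g in self.group_sizes],
                "p_value": self.p_values,
                "odds_ratio": self.odds_ratios,
            }
        )


def scan_vaf_cutoffs(
    samples: CohortTable, min_per_side: int = 5
) -> CutoffScanResult:
    """Scan all VAF cutpoints for maximal difference in MGMT positivity.

    Candidates are midpoints between consecutive distinct VAFs (so >= / <
    assignment is unambiguous) leaving at least ``min_per_side`` samples on
    each side. The optimal cutpoint minimizes the two-sided Fisher p; ties
    break toward the smallest cutoff. The scan is deterministic.
    """
    usable = [
        s for s in samples if s.mgmt_call in (Call.POSITIVE, Call.NEGATIVE)
    ]
    if len(usable) < 2 * min_per_side:
        raise ValueError(
            f"need at least {2 * min_per_side} binary-call samples, got {len(usable)}"
        )
    vafs = np.array([s.driver_vaf for s in usable])
    pos = np.array([s.mgmt_call is Call.POSITIVE for s in usable])
    order = np.argsort(vafs, kind="stable")
    vafs, pos = vafs[order], pos[order]
    distinct = np.unique(vafs)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0

    candidates, ps, ors, sizes = [], [], [], []
    for cut in midpoints:
        above = vafs >= cut
        n_above, n_below = int(above.sum()), int((~above).sum())
        if n_above < min_per_side or n_below < min_per_side:
            continue
        tab = Fisher2x2(
            a=int(pos[above].sum()),
            b=int(n_above - pos[above].sum()),
            c=int(pos[~above].sum()),
            d=int(n_below - pos[~above].sum()),
        )
        odds_ratio, p = fisher_exact(tab)
        candidates.append(float(cut))
        ps.append(p)
        ors.append(odds_ratio)
        sizes.append((n_above, n_below))
    if not candidates:
        raise ValueError(
            "no admissible cutpoint leaves "
            f"{min_per_side} samples on each side"
        )
    degenerate = bool(pos.all() or (~pos).all())
    best = int(np.argmin(ps))  # argmin takes the first minimum: smallest cutoff
    return CutoffScanResult(
        candidates=np.array(candidates),
        p_values=np.array(ps),
        odds_ratios=np.array(ors),
        group_sizes=sizes,
        optimal_cutoff=candidates[best],
        optimal_p=ps[best],
        degenerate=degenerate,
        min_per_side=min_per_side,
    )


def compare_groups(x_above, x_below, method: str = "t_test") -> float:
    """Two-sided p-value comparing two groups of scores.

    ``t_test`` is the unpaired Student's t-test; ``mann_whitney`` is the
    Wilcoxon rank-sum test (exact for small untied samples, tie-corrected
    normal approximation otherwise).
    """
    x_above = np.asarray(x_above, dtype=float)
    x_below = np.asarray(x_below, dtype=float)
    if x_above.size < 2 or x_below.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "t_test":
        if np.ptp(x_above) == 0 and np.ptp(x_below) == 0:
            # zero pooled variance: identical constants -> no evidence
            if x_above[0] == x_below[0]:
                return 1.0
        res = stats.ttest_ind(x_above, x_below, equal_var=True)
        return float(res.pvalue)
    if method == "mann_whitney":
        res = stats.mannwhitneyu(x_above, x_below, alternative="two-sided", method="auto")
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
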