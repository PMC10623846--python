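"""Cumulative statistics of MGMT results ranked by increasing driver VAF.

Samples are sorted by increasing VAF (stable, ties broken by sample id) and
the running mean positivity rate — or running mean/median methylation score —
is computed over each prefix: point k summarizes the k lowest-VAF samples.
The final point therefore equals the whole-cohort statistic. Only points at
the end of a block of tied VAFs are invariant to the ordering within the tie.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Call, CohortTable

__all__ = ["Statistic", "CumulativeCurve", "cumulative_positivity", "cumulative_score"]


class Statistic(str, enum.Enum):
    MEAN_POSITIVITY = "MEAN_POSITIVITY"
    MEAN_SCORE = "MEAN_SCORE"
    MEDIAN_SCORE = "MEDIAN_SCORE"


@dataclass
class CumulativeCurve:
    """A VAF-ranked cumulative curve: paired vectors of sorted VAFs and the
    running statistic over all samples up to and including each VAF."""

    vaf_ranked: np.ndarray
    cumulative_value: np.ndarray
    statistic: Statistic
    n_at_point: np.ndarray

    def __post_init__(self) -> None:
        self.vaf_ranked = np.asarray(self.vaf_ranked, dtype=float)
        self.cumulative_value = np.asarray(self.cumulative_value, dtype=float)
        self.n_at_point = np.asarray(self.n_at_point, dtype=int)
        k = self.vaf_ranked.size
        if self.cumulative_value.size != k or self.n_at_point.size != k:
            raise ValueError("curve vectors must have equal length")
        if k and np.any(np.diff(self.vaf_ranked) < 0):
            raise ValueError("vaf_ranked must be nondecreasing")
        if self.statistic is Statistic.MEAN_POSITIVITY and k:
            lo, hi = self.cumulative_value.min(), self.cumulative_value.max()
            if lo < -1e-12 or hi > 1 + 1e-12:
                raise ValueError("positivity values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.vaf_ranked.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vaf": self.vaf_ranked,
                "value": self.cumulative_value,
                "n": self.n_at_point,
            }
        )


def _ranked_binary(samples: CohortTable) -> list:
    usable, dropped = [], 0
    for s in samples:
        if s.mgmt_call in (Call.POSITIVE, Call.NEGATIVE):
            usable.append(s)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"excluded {dropped} sample(s) with EQUIVOCAL/QNS calls from the "
            "cumulative curve",
            stacklevel=3,
        )
    if not usable:
        raise ValueError("no samples with binary POSITIVE/NEGATIVE calls")
    return sorted(usable, key=lambda s: (s.driver_vaf, s.sample_id))


def cumulative_positivity(samples: CohortTable) -> CumulativeCurve:
    """Running mean positivity rate over VAF-ranked samples.

    Point k is the fraction of POSITIVE calls among the k lowest-VAF samples
    (POSITIVE = 1, NEGATIVE = 0). EQUIVOCAL and QNS samples are excluded with
    a warning.
    """
    ranked = _ranked_binary(samples)
    calls = np.array([1.0 if s.mgmt_call is Call.POSITIVE else 0.0 for s in ranked])
    k = np.arange(1, calls.size + 1)
    return CumulativeCurve(
        vaf_ranked=np.array([s.driver_vaf for s in ranked]),
        cumulative_value=np.cumsum(calls) / k,
        statistic=Statistic.MEAN_POSITIVITY,
        n_at_point=k,
    )


def cumulative_score(samples: CohortTable, stat: str = "mean") -> CumulativeCurve:
    """Running mean or median MGMT score over VAF-ranked samples.

    Even-length prefixes use the midpoint of the middle two for the median.
    Samples lacking a score or with EQUIVOCAL/QNS calls are excluded.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    with_scores = CohortTable(
        [s for s in samples if s.mgmt_score is not None],
        provenance=samples.provenance,
    )
    ranked = _ranked_binary(with_scores)
    scores = np.array([s.mgmt_score for s in ranked], dtype=float)
    k = np.arange(1, scores.size + 1)
    if stat == "mean":
        values = np.cumsum(scores) / k
        statistic = Statistic.MEAN_SCORE
    else:
        values = np.array([np.median(scores[: i + 1]) for i in range(scores.size)])
        statistic = Statistic.MEDIAN_SCORE
    return CumulativeCurve(
        vaf_ranked=np.array([s.driver_vaf for s in ranked]),
        cumulative_value=values,
        statistic=statistic,
        n_at_point=k,
    )
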