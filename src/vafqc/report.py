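"""False-negative risk flagging, assay comparisons, and the pipeline report.

A negative MGMT call on a specimen whose driver VAF falls below its
subtype-specific reliability cutoff may reflect dilution of the tumor's
methylation signal by non-neoplastic DNA rather than a truly unmethylated
promoter; such samples are flagged for orthogonal re-testing (methylation
array and/or ddPCR). Two cutoff sets ship by default: the two-part-regression
inflection points (GBM 0.18, astrocytoma 0.325, oligodendroglioma 0.30) and
the Fisher-exact scan optima (0.115 / 0.325 / 0.405); every report names the
set it used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .changepoint import two_part_fit
from .cohort import Call, CohortTable, Subtype, summarize_cohort
from .curves import cumulative_positivity, cumulative_score
from .cutpoints import Fisher2x2, fisher_exact, scan_vaf_cutoffs

__all__ = [
    "REGRESSION_CUTOFFS",
    "CUTOFF_FINDER_CUTOFFS",
    "RiskFlagReport",
    "AssayComparison",
    "flag_false_negative_risk",
    "estimate_fn_rate",
    "assay_comparison",
    "run_report",
]

# Subtype-specific VAF reliability cutoffs (see module docstring).
REGRESSION_CUTOFFS: dict[Subtype, float] = {
    Subtype.GBM_IDHWT: 0.18,
    Subtype.ASTRO_IDHMUT: 0.325,
    Subtype.OLIGO_IDHMUT_CODEL: 0.30,
}
CUTOFF_FINDER_CUTOFFS: dict[Subtype, float] = {
    Subtype.GBM_IDHWT: 0.115,
    Subtype.ASTRO_IDHMUT: 0.325,
    Subtype.OLIGO_IDHMUT_CODEL: 0.405,
}

_RECOMMENDATION = (
    "Recommend orthogonal re-testing by DNA methylation array and/or ddPCR: "
    "negative call with driver VAF below the subtype reliability cutoff may "
    "be a dilution false negative."
)


@dataclass
class RiskFlagReport:
    table: pd.DataFrame
    cutoffs: dict[str, float]
    cutoff_set: str
    n_flagged: int


@dataclass(frozen=True)
class AssayComparison:
    label_a: str
    label_b: str
    positive_a: int
    total_a: int
    percent_a: int
    positive_b: int
    total_b: int
    percent_b: int
    odds_ratio: float
    p_value: float


def flag_false_negative_risk(
    samples: CohortTable,
    cutoffs: Optional[Mapping[Subtype, float]] = None,
    cutoff_set: str = "regression",
) -> RiskFlagReport:
    """Flag samples at risk of a dilution false negative.

    A sample is flagged iff its call is NEGATIVE and its driver VAF is below
    the cutoff for its subtype. ``cutoffs`` overrides the named default set
    (``"regression"`` or ``"cutoff_finder"``); a subtype present in the
    cohort but absent from the cutoff map is an error.
    """
    if cutoffs is None:
        if cutoff_set == "regression":
            cutoffs = REGRESSION_CUTOFFS
        elif cutoff_set == "cutoff_finder":
            cutoffs = CUTOFF_FINDER_CUTOFFS
        else:
            raise ValueError(f"unknown cutoff_set {cutoff_set!r}")
    else:
        cutoff_set = "custom"
    observed = {s.subtype for s in samples}
    missing = [st.value for st in observed if st not in cutoffs]
    if missing:
        raise ValueError(f"no cutoff provided for subtype(s): {missing}")
    rows = []
    for s in samples:
        cut = cutoffs[s.subtype]
        flagged = s.mgmt_call is Call.NEGATIVE and s.driver_vaf < cut
        if flagged:
            reason = (
                f"NEGATIVE call with driver VAF {s.driver_vaf:g} < "
                f"{cut:g} ({s.subtype.value} cutoff, {cutoff_set} set)"
            )
            recommendation = _RECOMMENDATION
        else:
            reason = ""
            recommendation = ""
        rows.append(
            {
                "sample_id": s.sample_id,
                "subtype": s.subtype.value,
                "mgmt_call": s.mgmt_call.value,
                "driver_vaf": s.driver_vaf,
                "subtype_cutoff_used": cut,
                "flagged": flagged,
                "reason": reason,
                "recommendation": recommendation,
            }
        )
    table = pd.DataFrame(rows)
    return RiskFlagReport(
        table=table,
        cutoffs={st.value: float(v) for st, v in cutoffs.items()},
        cutoff_set=cutoff_set,
        n_flagged=int(table["flagged"].sum()) if len(table) else 0,
    )


def estimate_fn_rate(
    frac_below_cutoff: float, methylation_prevalence: float
) -> float:
    """Cohort-level false-negative rate estimate.

    The fraction of samples below the VAF reliability cutoff times the known
    methylation prevalence: the expected proportion of all tested samples
    that are truly methylated yet assayed in the unreliable low-purity
    regime.
    """
    for name, v in (
        ("frac_below_cutoff", frac_below_cutoff),
        ("methylation_prevalence", methylation_prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    return frac_below_cutoff * methylation_prevalence


def format_rate_percent(rate: float) -> str:
    """Human-readable percent with 1 decimal, e.g. 0.0441 -> '4.4%'."""
    return f"{rate * 100:.1f}%"


def assay_comparison(
    table: Fisher2x2, labels: tuple[str, str] = ("assay A", "assay B")
) -> AssayComparison:
    """Labeled positivity comparison between two assays (or strata).

    Rows of ``table`` are the two assays, columns positive/negative. Percents
    are rounded to integers for display; the odds ratio and two-sided Fisher
    p keep full precision. A row with zero total is an error.
    """
    total_a = table.a + table.b
    total_b = table.c + table.d
    if total_a == 0 or total_b == 0:
        raise ValueError("each comparison row needs at least one observation")
    odds_ratio, p = fisher_exact(table)
    return AssayComparison(
        label_a=labels[0],
        label_b=labels[1],
        positive_a=table.a,
        total_a=total_a,
        percent_a=int(round(100.0 * table.a / total_a)),
        positive_b=table.c,
        total_b=total_b,
        percent_b=int(round(100.0 * table.c / total_b)),
        odds_ratio=odds_ratio,
        p_value=p,
    )


def _regression_to_dict(fit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "p_slope": fit.p_slope,
        "n": fit.n,
    }


def run_report(
    cohort: CohortTable,
    out_dir: str | Path,
    cutoff_set: str = "regression",
    min_per_side: int = 5,
    min_seg: int | None = None,
) -> dict:
    """Full pipeline on one cohort: curves, cutpoint scan, changepoint,
    false-negative flags; writes a deterministic JSON + TSV bundle.

    Outputs (under ``out_dir``): ``report.json`` (machine-readable summary,
    sorted keys, no timestamps), ``curve_positivity.tsv``,
    ``scan_candidates.tsv``, ``flags.tsv``. Byte-identical across reruns on
    identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    binary = cohort.binary()
    if len(binary) == 0:
        raise ValueError("cohort has no binary-call samples")

    curve = cumulative_positivity(binary)
    curve.to_frame().to_csv(out / "curve_positivity.tsv", sep="\t", index=False)

    report: dict = {
        "provenance": cohort.provenance,
        "n_samples": len(cohort),
        "n_binary": len(binary),
        "cutoff_set": cutoff_set,
        "summary": json.loads(summarize_cohort(cohort).to_json()),
        "caveats": [
            "optimal cutpoint p-values are raw minima over all candidates; "
            "no multiple-testing correction is applied"
        ],
    }
    try:
        scan = scan_vaf_cutoffs(binary, min_per_side=min_per_side)
        scan.to_frame().to_csv(out / "scan_candidates.tsv", sep="\t", index=False)
        report["scan"] = {
            "optimal_cutoff": scan.optimal_cutoff,
            "optimal_p": scan.optimal_p,
            "degenerate": scan.degenerate,
            "n_candidates": int(scan.candidates.size),
            "min_per_side": min_per_side,
        }
    except ValueError as e:
        report["scan"] = {"error": str(e)}
    try:
        cp = two_part_fit(curve, min_seg=min_seg)
        report["changepoint"] = {
            "split_vaf": cp.split_vaf,
            "slope_difference": cp.slope_difference,
            "low_fit": _regression_to_dict(cp.low_fit),
            "high_fit": _regression_to_dict(cp.high_fit),
            "candidates_evaluated": cp.candidates_evaluated,
            "min_seg": min_seg if min_seg is not None else "adaptive",
        }
    except ValueError as e:
        report["changepoint"] = {"error": str(e)}

    flags = flag_false_negative_risk(cohort, cutoff_set=cutoff_set)
    flags.table.to_csv(out / "flags.tsv", sep="\t", index=False)
    report["flags"] = {
        "cutoffs": flags.cutoffs,
        "cutoff_set": flags.cutoff_set,
        "n_flagged": flags.n_flagged,
    }
    text = json.dumps(report, sort_keys=True, indent=2)
    (out / "report.json").write_text(text + "\n", encoding="utf-8")
    return report
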