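"""MGMT promoter methylation call rules for the three assays.

* Pyrosequencing: mean percent methylation over the assayed CpG sites,
  positive at >= 10% by the widely used clinical convention (a 7.28% cutoff,
  used in the original array-validation work, is supported as an alternative).
* Methylation array: the MGMT-STP27 logistic model on the M-values of probes
  cg12434587 and cg12981137; the MGMT score is the logit of the predicted
  probability of promoter methylation.
* ddPCR: percent methylated template, positive at >= 4.0%.

All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "PYRO_CUTOFF_CLINICAL",
    "PYRO_CUTOFF_BADY_VALIDATION",
    "DDPCR_CUTOFF",
    "BadyModel",
    "BadyResult",
    "PyroCall",
    "call_pyro",
    "call_bady",
    "call_ddpcr",
    "beta_to_m",
    "m_from_intensities",
    "load_bady_model",
]

PYRO_CUTOFF_CLINICAL = 10.0
PYRO_CUTOFF_BADY_VALIDATION = 7.28
DDPCR_CUTOFF = 4.0

# Array probes interrogated by the STP27 model (and by the ddPCR assay).
CPG_SITE_1 = "cg12434587"
CPG_SITE_2 = "cg12981137"


class SimpleCall(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EQUIVOCAL = "EQUIVOCAL"


@dataclass(frozen=True)
class BadyModel:
    """MGMT-STP27 logistic model: logit(p) = intercept + c1*M1 + c2*M2.

    ``prob_cutoff`` dichotomizes the predicted probability; an optional
    symmetric ``equivocal_halfwidth`` band around the cutoff yields
    EQUIVOCAL calls (default 0, i.e. binary calls).
    """

    intercept: float
    coef_cg12434587: float
    coef_cg12981137: float
    prob_cutoff: float = 0.358
    equivocal_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_cutoff < 1.0:
            raise ValueError(f"prob_cutoff {self.prob_cutoff} outside (0, 1)")
        if not 0.0 <= self.equivocal_halfwidth < min(
            self.prob_cutoff, 1.0 - self.prob_cutoff
        ):
            raise ValueError(
                "equivocal_halfwidth must satisfy "
                "0 <= h < min(prob_cutoff, 1 - prob_cutoff)"
            )


@dataclass(frozen=True)
class BadyResult:
    probability: float
    logit_score: float
    call: SimpleCall


@dataclass(frozen=True)
class PyroCall:
    score: float
    call: SimpleCall
    cutoff_used: float


def load_bady_model(path: Optional[str | Path] = None) -> BadyModel:
    """Load an STP27 model from a JSON (or YAML) config file.

    Without a path, returns the packaged default model (coefficients
    transcribed from the published MGMT-STP27 fit of the mgmtstp27 R package).
    """
    if path is None:
        text = (
            resources.files("vafqc").joinpath("data/mgmt_stp27.json").read_text()
        )
        cfg = json.loads(text)
    else:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    return BadyModel(
        intercept=float(cfg["intercept"]),
        coef_cg12434587=float(cfg["coef_cg12434587"]),
        coef_cg12981137=float(cfg["coef_cg12981137"]),
        prob_cutoff=float(cfg.get("prob_cutoff", 0.358)),
        equivocal_halfwidth=float(cfg.get("equivocal_halfwidth", 0.0)),
    )


def call_pyro(
    site_percents: Sequence[float] | float, cutoff: float = PYRO_CUTOFF_CLINICAL
) -> PyroCall:
    """Call pyrosequencing MGMT status from per-CpG methylation percentages.

    The score is the arithmetic mean of the 1-8 site values (a single
    aggregate value may be passed directly); POSITIVE iff score >= cutoff.
    """
    if isinstance(site_percents, (int, float)):
        site_percents = [float(site_percents)]
    values = [float(v) for v in site_percents]
    if not values:
        raise ValueError("site_percents must contain at least one value")
    if len(values) > 8:
        raise ValueError(f"expected at most 8 site values, got {len(values)}")
    for v in values:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"site percent {v} outside [0, 100]")
    score = sum(values) / len(values)
    call = SimpleCall.POSITIVE if score >= cutoff else SimpleCall.NEGATIVE
    return PyroCall(score=score, call=call, cutoff_used=cutoff)


def call_bady(m1: float, m2: float, model: Optional[BadyModel] = None) -> BadyResult:
    """Apply the STP27 logistic model to the M-values of the two probes.

    The logit score is the linear predictor itself, which equals
    ln(p / (1 - p)) exactly and stays finite where the probability saturates
    in floating point.
    """
    if model is None:
        model = load_bady_model()
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValueError(f"M-values must be finite, got ({m1}, {m2})")
    eta = model.intercept + model.coef_cg12434587 * m1 + model.coef_cg12981137 * m2
    # numerically stable logistic on both tails
    if eta >= 0:
        probability = 1.0 / (1.0 + math.exp(-eta))
    else:
        e = math.exp(eta)
        probability = e / (1.0 + e)
    if probability >= model.prob_cutoff + model.equivocal_halfwidth:
        call = SimpleCall.POSITIVE
    elif probability <= model.prob_cutoff - model.equivocal_halfwidth:
        call = SimpleCall.NEGATIVE
    else:
        call = SimpleCall.EQUIVOCAL
    return BadyResult(probability=probability, logit_score=eta, call=call)


def call_ddpcr(meth_percent: float, cutoff: float = DDPCR_CUTOFF) -> SimpleCall:
    """ddPCR call: POSITIVE iff percent methylated template >= cutoff."""
    if not 0.0 <= meth_percent <= 100.0:
        raise ValueError(f"meth_percent {meth_percent} outside [0, 100]")
    return SimpleCall.POSITIVE if meth_percent >= cutoff else SimpleCall.NEGATIVE


def beta_to_m(beta: float) -> float:
    """Convert a methylation beta value (fraction methylated) to an M-value.

    M = log2(beta / (1 - beta)); the exact inverse of
    beta = 2**M / (1 + 2**M).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta {beta} outside open interval (0, 1)")
    return math.log2(beta / (1.0 - beta))


def m_from_intensities(meth: float, unmeth: float, alpha: float = 1.0) -> float:
    """M-value from raw methylated/unmethylated intensities with offset alpha:
    log2((meth + alpha) / (unmeth + alpha))."""
    if meth < 0 or unmeth < 0:
        raise ValueError("intensities must be nonnegative")
    return math.log2((meth + alpha) / (unmeth + alpha))
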