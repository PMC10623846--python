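"""Cohort data model, validation, and delimited-text I/O.

A cohort table holds one row per tumor specimen: WHO subtype, driver-mutation
variant allelic frequency (VAF), the MGMT promoter methylation assay used
(pyrosequencing, EPIC methylation array, or ddPCR), the methylation score and
clinical call, plus optional annotations (microscopic cellularity estimate,
methylation-classifier score, sex, age, grade, recurrence status).

Files are UTF-8, tab- or comma-delimited (auto-detected from the header line),
with missing optional values encoded as empty strings. Enum tokens are read
case-insensitively and written in canonical uppercase.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import json
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "Subtype",
    "DriverGene",
    "Assay",
    "Call",
    "GliomaSample",
    "CohortTable",
    "CohortSummary",
    "CohortError",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]


class CohortError(Exception):
    """Base class for cohort-table errors."""


class SchemaError(CohortError):
    """A mandatory column is missing or the header is malformed."""


class ValidationError(CohortError):
    """One or more rows violate a sample invariant; message lists each row."""


class Subtype(str, enum.Enum):
    """Adult-type diffuse glioma subtypes (2021 WHO)."""

    GBM_IDHWT = "GBM_IDHWT"
    ASTRO_IDHMUT = "ASTRO_IDHMUT"
    OLIGO_IDHMUT_CODEL = "OLIGO_IDHMUT_CODEL"


class DriverGene(str, enum.Enum):
    TERTP = "TERTP"
    IDH1 = "IDH1"
    IDH2 = "IDH2"


class Assay(str, enum.Enum):
    PYRO = "PYRO"
    ARRAY = "ARRAY"
    DDPCR = "DDPCR"


class Call(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EQUIVOCAL = "EQUIVOCAL"
    QNS = "QNS"  # quantity/quality of DNA not sufficient


# Genes compatible with each subtype: TERT-promoter-mutant IDH-wildtype GBM
# only; IDH1/IDH2 for the two IDH-mutant subtypes.
_SUBTYPE_GENES = {
    Subtype.GBM_IDHWT: {DriverGene.TERTP},
    Subtype.ASTRO_IDHMUT: {DriverGene.IDH1, DriverGene.IDH2},
    Subtype.OLIGO_IDHMUT_CODEL: {DriverGene.IDH1, DriverGene.IDH2},
}

_DEFAULT_GENE = {
    Subtype.GBM_IDHWT: DriverGene.TERTP,
    Subtype.ASTRO_IDHMUT: DriverGene.IDH1,
    Subtype.OLIGO_IDHMUT_CODEL: DriverGene.IDH1,
}

COLUMNS = [
    "sample_id",
    "subtype",
    "driver_gene",
    "driver_vaf",
    "assay",
    "mgmt_score",
    "mgmt_call",
    "site_percents",
    "micro_cellularity",
    "classifier_score",
    "sex",
    "age",
    "who_grade",
    "is_recurrent",
]

MANDATORY_COLUMNS = ["sample_id", "subtype", "driver_vaf", "assay", "mgmt_call"]


@dataclass(frozen=True)
class GliomaSample:
    """One tumor specimen with its driver VAF and MGMT assay result.

    ``site_percents`` carries the per-CpG methylation percentages of the
    4-CpG pyrosequencing assay; when present with ``assay=PYRO`` the
    ``mgmt_score`` must equal their arithmetic mean (within 0.01).
    """

    sample_id: str
    subtype: Subtype
    driver_vaf: float
    assay: Assay
    mgmt_call: Call
    driver_gene: Optional[DriverGene] = None
    mgmt_score: Optional[float] = None
    site_percents: Optional[tuple[float, ...]] = None
    micro_cellularity: Optional[float] = None
    classifier_score: Optional[float] = None
    sex: Optional[str] = None
    age: Optional[int] = None
    who_grade: Optional[int] = None
    is_recurrent: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if not 0.0 <= self.driver_vaf <= 1.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: driver_vaf {self.driver_vaf} "
                "outside [0, 1]"
            )
        gene = self.driver_gene
        if gene is None:
            object.__setattr__(self, "driver_gene", _DEFAULT_GENE[self.subtype])
        elif gene not in _SUBTYPE_GENES[self.subtype]:
            raise ValidationError(
                f"sample {self.sample_id!r}: driver gene {gene.value} "
                f"incompatible with subtype {self.subtype.value}"
            )
        if self.site_percents is not None:
            object.__setattr__(
                self, "site_percents", tuple(float(v) for v in self.site_percents)
            )
            for v in self.site_percents:
                if not 0.0 <= v <= 100.0:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: site percent {v} "
                        "outside [0, 100]"
                    )
            if self.assay is Assay.PYRO and self.mgmt_score is not None:
                mean = sum(self.site_percents) / len(self.site_percents)
                if abs(mean - self.mgmt_score) > 0.01:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: mgmt_score "
                        f"{self.mgmt_score} differs from site mean {mean:.4f} "
                        "by more than 0.01"
                    )
        if self.micro_cellularity is not None and not (
            0.0 <= self.micro_cellularity <= 100.0
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: micro_cellularity "
                f"{self.micro_cellularity} outside [0, 100]"
            )
        if self.classifier_score is not None and not (
            0.0 <= self.classifier_score <= 1.0
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: classifier_score "
                f"{self.classifier_score} outside [0, 1]"
            )
        if self.mgmt_score is not None and self.assay is not Assay.ARRAY:
            # pyro/ddPCR scores are percent methylation
            if not 0.0 <= self.mgmt_score <= 100.0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: mgmt_score {self.mgmt_score} "
                    "outside [0, 100]"
                )


@dataclass
class CohortTable:
    """An ordered collection of :class:`GliomaSample` with unique ids."""

    samples: list[GliomaSample] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[GliomaSample]:
        return iter(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.samples == other.samples

    def without_qns(self) -> "CohortTable":
        """Samples with a QNS call are retained in the table but excluded
        from every downstream statistic; this is the downstream view."""
        return CohortTable(
            [s for s in self.samples if s.mgmt_call is not Call.QNS],
            provenance=self.provenance,
        )

    def binary(self) -> "CohortTable":
        """Samples with an unambiguous POSITIVE/NEGATIVE call."""
        return CohortTable(
            [
                s
                for s in self.samples
                if s.mgmt_call in (Call.POSITIVE, Call.NEGATIVE)
            ],
            provenance=self.provenance,
        )

    def subset(self, subtype: Subtype) -> "CohortTable":
        return CohortTable(
            [s for s in self.samples if s.subtype is subtype],
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "subtype": s.subtype.value,
                    "driver_gene": s.driver_gene.value if s.driver_gene else None,
                    "driver_vaf": s.driver_vaf,
                    "assay": s.assay.value,
                    "mgmt_score": s.mgmt_score,
                    "mgmt_call": s.mgmt_call.value,
                    "micro_cellularity": s.micro_cellularity,
                    "classifier_score": s.classifier_score,
                    "sex": s.sex,
                    "age": s.age,
                    "who_grade": s.who_grade,
                    "is_recurrent": s.is_recurrent,
                }
            )
        return pd.DataFrame(rows, columns=[c for c in COLUMNS if c != "site_percents"])


@dataclass
class CohortSummary:
    """Descriptive cohort summary: counts and per-subtype VAF statistics."""

    n: int
    by_subtype: dict[str, int]
    by_sex: dict[str, int]
    by_grade: dict[str, int]
    by_assay: dict[str, int]
    by_call: dict[str, int]
    vaf_by_subtype: dict[str, dict[str, float]]
    vaf_overall: Optional[dict[str, float]]

    @property
    def empty(self) -> bool:
        return self.n == 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, sort_keys=True, **kwargs)


def _vaf_stats(vafs: Sequence[float]) -> dict[str, float]:
    return {
        "mean": float(sum(vafs) / len(vafs)),
        "median": float(statistics.median(vafs)),
        "min": float(min(vafs)),
        "max": float(max(vafs)),
        "n": len(vafs),
    }


def summarize_cohort(table: CohortTable) -> CohortSummary:
    """Exact counts and order statistics; the median of an even-sized set is
    the midpoint of the middle two. An empty table yields an empty-summary
    marker rather than an error."""
    if len(table) == 0:
        return CohortSummary(0, {}, {}, {}, {}, {}, {}, None)
    by_subtype: dict[str, int] = {}
    by_sex: dict[str, int] = {}
    by_grade: dict[str, int] = {}
    by_assay: dict[str, int] = {}
    by_call: dict[str, int] = {}
    vafs_by_subtype: dict[str, list[float]] = {}
    all_vafs: list[float] = []
    for s in table:
        by_subtype[s.subtype.value] = by_subtype.get(s.subtype.value, 0) + 1
        if s.sex is not None:
            by_sex[s.sex] = by_sex.get(s.sex, 0) + 1
        if s.who_grade is not None:
            key = str(s.who_grade)
            by_grade[key] = by_grade.get(key, 0) + 1
        by_assay[s.assay.value] = by_assay.get(s.assay.value, 0) + 1
        by_call[s.mgmt_call.value] = by_call.get(s.mgmt_call.value, 0) + 1
        vafs_by_subtype.setdefault(s.subtype.value, []).append(s.driver_vaf)
        all_vafs.append(s.driver_vaf)
    return CohortSummary(
        n=len(table),
        by_subtype=by_subtype,
        by_sex=by_sex,
        by_grade=by_grade,
        by_assay=by_assay,
        by_call=by_call,
        vaf_by_subtype={k: _vaf_stats(v) for k, v in vafs_by_subtype.items()},
        vaf_overall=_vaf_stats(all_vafs),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def _parse_enum(cls, token: str, row: int, column: str):
    try:
        return cls[token.strip().upper()]
    except KeyError:
        valid = ", ".join(m.name for m in cls)
        raise ValidationError(
            f"row {row}: unknown {column} token {token!r} (expected one of {valid})"
        ) from None


def _parse_float(token: str, row: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"row {row}: {column} {token!r} is not a number") from None


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cohort(path: str | Path, dialect: Optional[str] = None) -> CohortTable:
    """Read a cohort table from delimited text.

    Parameters
    ----------
    path
        UTF-8 text file with a header row naming at least
        ``sample_id, subtype, driver_vaf, assay, mgmt_call``. Column order is
        irrelevant; unknown columns are ignored.
    dialect
        Delimiter override (``"\\t"`` or ``","``); auto-detected from the
        header line when omitted.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    ValidationError
        If any row violates a sample invariant; the message names every
        offending row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header row")
    sep = dialect or _detect_delimiter(lines[0])
    reader = csv.reader(lines, delimiter=sep)
    header = [h.strip().lower() for h in next(reader)]
    missing = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    idx = {name: header.index(name) for name in COLUMNS if name in header}

    def get(record: list[str], column: str) -> str:
        i = idx.get(column)
        if i is None or i >= len(record):
            return ""
        return record[i].strip()

    samples: list[GliomaSample] = []
    errors: list[str] = []
    for rownum, record in enumerate(reader, start=2):
        if not any(cell.strip() for cell in record):
            continue
        try:
            subtype = _parse_enum(Subtype, get(record, "subtype"), rownum, "subtype")
            gene_tok = get(record, "driver_gene")
            gene = (
                _parse_enum(DriverGene, gene_tok, rownum, "driver_gene")
                if gene_tok
                else None
            )
            assay = _parse_enum(Assay, get(record, "assay"), rownum, "assay")
            call = _parse_enum(Call, get(record, "mgmt_call"), rownum, "mgmt_call")
            vaf = _parse_float(get(record, "driver_vaf"), rownum, "driver_vaf")
            score_tok = get(record, "mgmt_score")
            sites_tok = get(record, "site_percents")
            micro_tok = get(record, "micro_cellularity")
            clf_tok = get(record, "classifier_score")
            age_tok = get(record, "age")
            grade_tok = get(record, "who_grade")
            rec_tok = get(record, "is_recurrent")
            sample = GliomaSample(
                sample_id=get(record, "sample_id"),
                subtype=subtype,
                driver_gene=gene,
                driver_vaf=vaf,
                assay=assay,
                mgmt_score=_parse_float(score_tok, rownum, "mgmt_score")
                if score_tok
                else None,
                mgmt_call=call,
                site_percents=tuple(
                    _parse_float(v, rownum, "site_percents")
                    for v in sites_tok.split(";")
                )
                if sites_tok
                else None,
                micro_cellularity=_parse_float(micro_tok, rownum, "micro_cellularity")
                if micro_tok
                else None,
                classifier_score=_parse_float(clf_tok, rownum, "classifier_score")
                if clf_tok
                else None,
                sex=get(record, "sex").upper() or None,
                age=int(age_tok) if age_tok else None,
                who_grade=int(grade_tok) if grade_tok else None,
                is_recurrent={"TRUE": True, "FALSE": False, "1": True, "0": False}.get(
                    rec_tok.upper()
                )
                if rec_tok
                else None,
            )
        except ValidationError as e:
            msg = str(e)
            errors.append(msg if msg.startswith("row ") else f"row {rownum}: {msg}")
            continue
        samples.append(sample)
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]
    return CohortTable(samples, provenance=f"{path.name}:sha256:{digest}")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(
    table: CohortTable, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a cohort as delimited text re-readable by :func:`read_cohort`.

    Missing optional values are written as empty strings, never as zeros;
    floats use ``repr`` so the round trip is lossless.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(COLUMNS)
        for s in table:
            writer.writerow(
                [
                    s.sample_id,
                    s.subtype.value,
                    s.driver_gene.value if s.driver_gene else "",
                    _fmt(s.driver_vaf),
                    s.assay.value,
                    _fmt(s.mgmt_score),
                    s.mgmt_call.value,
                    ";".join(_fmt(v) for v in s.site_percents)
                    if s.site_percents is not None
                    else "",
                    _fmt(s.micro_cellularity),
                    _fmt(s.classifier_score),
                    s.sex or "",
                    _fmt(s.age),
                    _fmt(s.who_grade),
                    _fmt(s.is_recurrent),
                ]
            )
    return path
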