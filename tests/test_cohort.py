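"""Cohort data model, I/O round trips, validation, and summarization."""

import pytest
from hypothesis import given, strategies as st

from vafqc import (
    Assay,
    Call,
    CohortTable,
    DriverGene,
    GliomaSample,
    SchemaError,
    Subtype,
    ValidationError,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

HEADER = "sample_id\tsubtype\tdriver_gene\tdriver_vaf\tassay\tmgmt_score\tmgmt_call"


def _write(tmp_path, text, name="cohort.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadCohort:
    def test_header_only_gives_empty_table(self, tmp_path):
        table = read_cohort(_write(tmp_path, HEADER + "\n"))
        assert len(table) == 0

    def test_parses_low_vaf_positive_sample(self, tmp_path):
        # a positive call at score 11.06 is consistent with the 10.0 cutoff
        row = "Pyro-081\tGBM_IDHwt\tTERTp\t0.10\tPYRO\t11.06\tPOSITIVE"
        table = read_cohort(_write(tmp_path, HEADER + "\n" + row + "\n"))
        (s,) = table.samples
        assert s.sample_id == "Pyro-081"
        assert s.subtype is Subtype.GBM_IDHWT
        assert s.driver_vaf == 0.10
        assert s.mgmt_score == 11.06
        assert s.mgmt_call is Call.POSITIVE
        assert s.mgmt_score >= 10.0

    def test_comma_dialect_autodetected(self, tmp_path):
        text = HEADER.replace("\t", ",") + "\nS1,gbm_idhwt,tertp,0.2,pyro,5.0,negative\n"
        table = read_cohort(_write(tmp_path, text, "cohort.csv"))
        assert table.samples[0].assay is Assay.PYRO
        assert table.samples[0].mgmt_call is Call.NEGATIVE

    def test_column_order_insensitive(self, tmp_path):
        text = "mgmt_call\tdriver_vaf\tassay\tsubtype\tsample_id\nPOSITIVE\t0.3\tARRAY\tASTRO_IDHmut\tA1\n"
        table = read_cohort(_write(tmp_path, text))
        assert table.samples[0].sample_id == "A1"
        # driver_gene blank: defaulted consistently with subtype
        assert table.samples[0].driver_gene is DriverGene.IDH1

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="driver_vaf"):
            read_cohort(_write(tmp_path, "sample_id\tsubtype\tassay\tmgmt_call\n"))

    def test_vaf_out_of_range_names_row(self, tmp_path):
        text = HEADER + "\nS1\tGBM_IDHwt\tTERTp\t1.5\tPYRO\t5.0\tNEGATIVE\n"
        with pytest.raises(ValidationError, match="row 2"):
            read_cohort(_write(tmp_path, text))

    def test_unknown_enum_token_rejected(self, tmp_path):
        text = HEADER + "\nS1\tGBM_IDHwt\tTERTp\t0.2\tSANGER\t5.0\tNEGATIVE\n"
        with pytest.raises(ValidationError, match="SANGER"):
            read_cohort(_write(tmp_path, text))


class TestWriteCohort:
    def test_empty_table_writes_header_only(self, tmp_path):
        path = write_cohort(CohortTable([]), tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("sample_id\t")

    def test_round_trip_identity(self, small_cohort, tmp_path):
        path = write_cohort(small_cohort, tmp_path / "rt.tsv")
        assert read_cohort(path) == small_cohort

    def test_missing_optionals_stay_blank(self, small_cohort, tmp_path):
        path = write_cohort(small_cohort, tmp_path / "rt.tsv")
        # S3 has no micro_cellularity: the field must be empty, not 0
        row = [l for l in path.read_text().splitlines() if l.startswith("S3")][0]
        fields = row.split("\t")
        header = path.read_text().splitlines()[0].split("\t")
        assert fields[header.index("micro_cellularity")] == ""


class TestSampleInvariants:
    def test_subtype_gene_incompatibility(self):
        with pytest.raises(ValidationError, match="incompatible"):
            GliomaSample(
                sample_id="X",
                subtype=Subtype.GBM_IDHWT,
                driver_gene=DriverGene.IDH1,
                driver_vaf=0.3,
                assay=Assay.PYRO,
                mgmt_call=Call.NEGATIVE,
            )

    def test_site_mean_must_match_score(self):
        with pytest.raises(ValidationError, match="site mean"):
            GliomaSample(
                sample_id="X",
                subtype=Subtype.GBM_IDHWT,
                driver_vaf=0.3,
                assay=Assay.PYRO,
                mgmt_score=20.0,
                site_percents=(1.0, 2.0, 3.0, 4.0),
                mgmt_call=Call.NEGATIVE,
            )

    def test_duplicate_ids_rejected(self):
        s = GliomaSample(
            sample_id="X",
            subtype=Subtype.GBM_IDHWT,
            driver_vaf=0.3,
            assay=Assay.PYRO,
            mgmt_call=Call.NEGATIVE,
        )
        with pytest.raises(ValidationError, match="duplicate"):
            CohortTable([s, s])

    def test_qns_retained_but_excluded_downstream(self):
        samples = [
            GliomaSample(
                sample_id=f"S{i}",
                subtype=Subtype.GBM_IDHWT,
                driver_vaf=0.3,
                assay=Assay.PYRO,
                mgmt_call=call,
            )
            for i, call in enumerate([Call.POSITIVE, Call.QNS, Call.NEGATIVE])
        ]
        table = CohortTable(samples)
        assert len(table) == 3
        assert len(table.without_qns()) == 2
        assert len(table.binary()) == 2


class TestSummarize:
    def test_retest_cohort_counts_and_median(self, retest_cohort):
        summary = summarize_cohort(retest_cohort)
        assert summary.by_sex == {"M": 4, "F": 8}
        # sorted VAFs: 0.02,0.02,0.04,0.07,0.10,0.10,0.25,0.28,0.35,0.44,0.49,0.78
        assert summary.vaf_overall["median"] == pytest.approx(0.175)
        assert summary.n == 12

    def test_single_sample_statistics_collapse(self):
        table = CohortTable(
            [
                GliomaSample(
                    sample_id="S1",
                    subtype=Subtype.OLIGO_IDHMUT_CODEL,
                    driver_vaf=0.4,
                    assay=Assay.ARRAY,
                    mgmt_call=Call.POSITIVE,
                )
            ]
        )
        stats = summarize_cohort(table).vaf_overall
        assert stats["mean"] == stats["median"] == stats["min"] == stats["max"] == 0.4

    def test_even_sized_median_is_midpoint(self):
        table = CohortTable(
            [
                GliomaSample(
                    sample_id=f"S{i}",
                    subtype=Subtype.GBM_IDHWT,
                    driver_vaf=v,
                    assay=Assay.PYRO,
                    mgmt_call=Call.NEGATIVE,
                )
                for i, v in enumerate([0.2, 0.4])
            ]
        )
        assert summarize_cohort(table).vaf_overall["median"] == pytest.approx(0.3)

    def test_empty_table_gives_empty_marker(self):
        summary = summarize_cohort(CohortTable([]))
        assert summary.empty
        assert summary.n == 0


# --- property tests -------------------------------------------------------

_subtype_gene = st.sampled_from(
    [
        (Subtype.GBM_IDHWT, DriverGene.TERTP),
        (Subtype.ASTRO_IDHMUT, DriverGene.IDH1),
        (Subtype.ASTRO_IDHMUT, DriverGene.IDH2),
        (Subtype.OLIGO_IDHMUT_CODEL, DriverGene.IDH1),
    ]
)


@st.composite
def cohort_tables(draw):
    n = draw(st.integers(min_value=0, max_value=8))
    samples = []
    for i in range(n):
        subtype, gene = draw(_subtype_gene)
        score = draw(
            st.one_of(st.none(), st.floats(0, 100, allow_nan=False, width=32))
        )
        samples.append(
            GliomaSample(
                sample_id=f"H{i}",
                subtype=subtype,
                driver_gene=gene,
                driver_vaf=draw(st.floats(0, 1, allow_nan=False, width=32)),
                assay=draw(st.sampled_from(list(Assay))),
                mgmt_score=float(score) if score is not None else None,
                mgmt_call=draw(st.sampled_from(list(Call))),
                micro_cellularity=draw(
                    st.one_of(st.none(), st.floats(0, 100, allow_nan=False, width=32))
                ),
                sex=draw(st.sampled_from(["M", "F", None])),
            )
        )
    return CohortTable(samples)


@given(cohort_tables())
def test_round_trip_identity_on_random_tables(tmp_path_factory, table):
    path = tmp_path_factory.mktemp("rt") / "cohort.tsv"
    write_cohort(table, path)
    assert read_cohort(path) == table


@given(cohort_tables())
def test_summary_counts_partition_table(table):
    summary = summarize_cohort(table)
    assert sum(summary.by_subtype.values()) == len(table)
    assert sum(summary.by_call.values()) == len(table)
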