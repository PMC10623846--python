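import hypothesis
import pytest

from vafqc import (
    Assay,
    Call,
    CohortTable,
    DriverGene,
    GliomaSample,
    Subtype,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


# A 12-sample IDH-wildtype GBM re-testing cohort: pyrosequencing score, call
# at the 10% cutoff, sex, age and TERT VAF per sample (6 low-VAF, 6 high-VAF).
RETEST_ROWS = [
    ("Pyro-311", "M", 61, 0.02, 1.49, Call.NEGATIVE),
    ("Pyro-293", "F", 55, 0.02, 6.44, Call.NEGATIVE),
    ("Pyro-049", "M", 53, 0.04, 5.52, Call.NEGATIVE),
    ("Pyro-023", "F", 47, 0.07, 3.73, Call.NEGATIVE),
    ("Pyro-081", "F", 69, 0.10, 11.06, Call.POSITIVE),
    ("Pyro-182", "F", 69, 0.10, 4.85, Call.NEGATIVE),
    ("Pyro-083", "F", 46, 0.25, 2.97, Call.NEGATIVE),
    ("Pyro-200", "M", 53, 0.28, 3.18, Call.NEGATIVE),
    ("Pyro-152", "F", 56, 0.35, 4.01, Call.NEGATIVE),
    ("Pyro-053", "F", 69, 0.44, 35.56, Call.POSITIVE),
    ("Pyro-417", "F", 69, 0.49, 3.20, Call.NEGATIVE),
    ("Pyro-243", "M", 61, 0.78, 3.03, Call.NEGATIVE),
]


@pytest.fixture
def retest_cohort() -> CohortTable:
    samples = [
        GliomaSample(
            sample_id=sid,
            subtype=Subtype.GBM_IDHWT,
            driver_gene=DriverGene.TERTP,
            driver_vaf=vaf,
            assay=Assay.PYRO,
            mgmt_score=score,
            mgmt_call=call,
            sex=sex,
            age=age,
        )
        for sid, sex, age, vaf, score, call in RETEST_ROWS
    ]
    return CohortTable(samples, provenance="retest-fixture")


@pytest.fixture
def small_cohort() -> CohortTable:
    """Three samples covering all subtypes and optional-field missingness."""
    return CohortTable(
        [
            GliomaSample(
                sample_id="S1",
                subtype=Subtype.GBM_IDHWT,
                driver_gene=DriverGene.TERTP,
                driver_vaf=0.31,
                assay=Assay.PYRO,
                mgmt_score=16.75,
                mgmt_call=Call.POSITIVE,
                site_percents=(12.0, 14.0, 16.0, 25.0),
                micro_cellularity=60.0,
                sex="F",
                age=64,
                who_grade=4,
                is_recurrent=False,
            ),
            GliomaSample(
                sample_id="S2",
                subtype=Subtype.ASTRO_IDHMUT,
                driver_gene=DriverGene.IDH1,
                driver_vaf=0.42,
                assay=Assay.ARRAY,
                mgmt_score=-1.3,
                mgmt_call=Call.NEGATIVE,
                classifier_score=0.97,
                who_grade=3,
            ),
            GliomaSample(
                sample_id="S3",
                subtype=Subtype.OLIGO_IDHMUT_CODEL,
                driver_gene=DriverGene.IDH2,
                driver_vaf=0.40,
                assay=Assay.DDPCR,
                mgmt_score=22.0,
                mgmt_call=Call.POSITIVE,
            ),
        ],
        provenance="small-fixture",
    )
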