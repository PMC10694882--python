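import pytest

from fourlocus import Cohort, Genotype, Group, SampleRecord, Sex
from fourlocus.datasets import HAN, KAZAK
from fourlocus.loci import PANEL, normalize_genotype


def make_sample(sample_id, group, genotypes, sex=Sex.UNKNOWN, age=None):
    """Build a SampleRecord from raw genotype strings keyed by gene name.

    ``genotypes`` maps gene -> two-character call (or "NA"); omitted loci
    default to the heterozygote so the record stays complete.
    """
    by_gene = {locus.gene: locus for locus in PANEL}
    calls = {}
    for locus in PANEL:
        raw = genotypes.get(locus.gene,
                            locus.risk_allele + locus.nonrisk_allele)
        calls[locus.rs_id] = normalize_genotype(raw, locus, context=sample_id)
    return SampleRecord(sample_id=sample_id, group=group, sex=sex,
                        age_years=age, genotypes=calls)


def profile_sample(sample_id, group, flags):
    """Sample whose risk profile equals ``flags`` (panel order)."""
    calls = {}
    for locus, flag in zip(PANEL, flags):
        raw = (locus.risk_allele * 2 if flag
               else locus.risk_allele + locus.nonrisk_allele)
        calls[locus.rs_id] = normalize_genotype(raw, locus)
    return SampleRecord(sample_id=sample_id, group=group, genotypes=calls)


@pytest.fixture(scope="session")
def han_counts():
    return HAN.genotype_counts()


@pytest.fixture(scope="session")
def kazak_counts():
    return KAZAK.genotype_counts()


@pytest.fixture(scope="session")
def han_cohort():
    return HAN.reference_cohort()


@pytest.fixture(scope="session")
def kazak_cohort():
    return KAZAK.reference_cohort()


@pytest.fixture
def tiny_cohort():
    """Two complete samples, one per group."""
    return Cohort(name="tiny", samples=[
        make_sample("s1", Group.ASTHMA,
                    {"ADRB2": "AA", "IL4": "TT", "FCER1B": "AG", "IL13": "GA"},
                    sex=Sex.MALE, age=7.0),
        make_sample("s2", Group.CONTROL,
                    {"ADRB2": "AG", "IL4": "TC", "FCER1B": "AA", "IL13": "AA"},
                    sex=Sex.FEMALE, age=5.5),
    ])
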