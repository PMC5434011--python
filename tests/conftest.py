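"""Shared fixtures: bundled tables/panels and hand-built pedigrees."""

import pytest

from rpscreen import io_formats
from rpscreen.models import (
    Affection,
    Consequence,
    Family,
    InheritanceModel,
    Individual,
    PolyphenCall,
    PredictionTriple,
    ProveanCall,
    Sex,
    SiftCall,
    VariantRecord,
    Zygosity,
)


@pytest.fixture(scope="session")
def known_rp_rows():
    return io_formats.load_known_rp_table()


@pytest.fixture(scope="session")
def other_retinopathy_rows():
    return io_formats.load_other_retinopathy_table()


@pytest.fixture(scope="session")
def rescue_rows():
    return io_formats.load_rescue_table()


@pytest.fixture(scope="session")
def known_panel():
    return io_formats.load_known_rp_panel()


@pytest.fixture(scope="session")
def other_panel():
    return io_formats.load_other_retinopathy_panel()


@pytest.fixture(scope="session")
def catalog():
    return io_formats.load_reported_catalog()


DAMAGING = PredictionTriple(
    ProveanCall.DELETERIOUS, SiftCall.DAMAGING,
    PolyphenCall.PROBABLY_DAMAGING,
)
BENIGN = PredictionTriple(
    ProveanCall.NEUTRAL, SiftCall.TOLERATED, PolyphenCall.BENIGN,
)


def make_variant(gene="USH2A", hgvs="c.1A>G",
                 consequence=Consequence.NONSYNONYMOUS,
                 predictions=DAMAGING, frequencies=None,
                 quality=None, depth=None, chrom="", pos=1):
    return VariantRecord(
        gene=gene, hgvs_c=hgvs, consequence=consequence,
        predictions=predictions, frequencies=frequencies or {},
        quality=quality, depth=depth, chrom=chrom or "chr1", pos=pos,
    )


def make_trio(family_id="T1", model=InheritanceModel.RECESSIVE,
              proband_sex=Sex.FEMALE,
              father_affected=False, mother_affected=False):
    """Trio with an affected, sequenced child."""
    father = Individual(f"{family_id}_f", family_id, sex=Sex.MALE,
                        affected=Affection.AFFECTED if father_affected
                        else Affection.UNAFFECTED)
    mother = Individual(f"{family_id}_m", family_id, sex=Sex.FEMALE,
                        affected=Affection.AFFECTED if mother_affected
                        else Affection.UNAFFECTED)
    child = Individual(f"{family_id}_p", family_id,
                       father_id=father.sample_id,
                       mother_id=mother.sample_id,
                       sex=proband_sex, affected=Affection.AFFECTED)
    return Family(family_id=family_id, members=[child, father, mother],
                  declared_model=model)


def set_genotypes(family, variant, **calls):
    """calls: member suffix ('p', 'f', 'm', 's') -> Zygosity."""
    for suffix, zygosity in calls.items():
        family.genotypes[
            (f"{family.family_id}_{suffix}", variant.key)
        ] = zygosity
    # everyone else explicitly homozygous reference
    for member in family.members:
        key = (member.sample_id, variant.key)
        family.genotypes.setdefault(key, Zygosity.HOM_REF)
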