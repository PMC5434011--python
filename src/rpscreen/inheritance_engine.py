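"""Inheritance-model matching, compound-het phasing and segregation rules.

Given a family's pedigree genotypes and the variants that survived the
filter cascade, this module forms :class:`~rpscreen.models.CandidateUnit`
hypotheses:

* dominant — one heterozygous allele in a gene with a dominant mode
  (possibly de novo when both parents are sequenced and homozygous
  reference);
* recessive_hom — a homozygous alternate allele in a recessive-mode gene;
* recessive_comphet — two distinct heterozygous alleles in a
  recessive-mode gene, phased in trans via parental or unaffected-relative
  genotypes where possible (pairs proven cis are rejected; singleton
  probands yield phase_unknown units);
* xlinked — a hemizygous allele in an affected male (or homozygous in an
  affected female; heterozygous affected females are emitted flagged
  low-confidence).

Every unit is checked for segregation: an unaffected sequenced relative
carrying the *full* causal genotype refutes the hypothesis, while an
unaffected carrier of half a recessive unit is expected and consistent.
"""

from __future__ import annotations

from itertools import combinations

from .filter_cascade import FilterPolicy, max_reference_maf, triple_benign
from .models import (
    Affection,
    CandidateUnit,
    Consequence,
    DeNovoStatus,
    Family,
    GenePanel,
    Individual,
    InheritanceModel,
    Mode,
    Phase,
    Segregation,
    Sex,
    UnitModel,
    VariantKey,
    VariantRecord,
    Zygosity,
)

TRUNCATING_LIKE = frozenset({
    Consequence.STOPGAIN,
    Consequence.STOPLOSS,
    Consequence.FRAMESHIFT_DELETION,
    Consequence.FRAMESHIFT_INSERTION,
    Consequence.SPLICING,
    Consequence.SPLICE_ACCEPTOR_REGION,
})

#: Unit models a family's declared inheritance class is scanned under.
#: Sporadic families are evaluated under every model: published solutions
#: for sporadic probands span dominant de novo, homozygous recessive,
#: compound-het and X-linked causes.
MODELS_BY_DECLARED = {
    InheritanceModel.DOMINANT: frozenset({UnitModel.DOMINANT}),
    InheritanceModel.RECESSIVE: frozenset({
        UnitModel.RECESSIVE_HOM, UnitModel.RECESSIVE_COMPHET}),
    InheritanceModel.XLINKED: frozenset({UnitModel.XLINKED}),
    InheritanceModel.SPORADIC: frozenset({
        UnitModel.DOMINANT, UnitModel.RECESSIVE_HOM,
        UnitModel.RECESSIVE_COMPHET, UnitModel.XLINKED}),
}

_MODE_FOR_MODEL = {
    UnitModel.DOMINANT: Mode.AD,
    UnitModel.RECESSIVE_HOM: Mode.AR,
    UnitModel.RECESSIVE_COMPHET: Mode.AR,
    UnitModel.XLINKED: Mode.XL,
}


def primary_proband(family: Family) -> Individual:
    probands = family.probands
    if not probands:
        raise ValueError(f"family {family.family_id} has no proband")
    return probands[0]


def match_inheritance(
    family: Family,
    gene: str,
    variants: list[VariantRecord],
    panel: GenePanel,
) -> list[UnitModel]:
    """Unit models compatible with both the gene's panel modes and the
    proband's genotypes at the given variants.

    A gene absent from the panel yields an empty list (not an error).
    """
    modes = panel.modes(gene)
    if not modes:
        return []
    proband = primary_proband(family)
    scanned = MODELS_BY_DECLARED[family.declared_model]
    zygosities = [family.genotype(proband.sample_id, v.key) for v in variants]
    n_het = sum(1 for z in zygosities if z is Zygosity.HET)
    out: list[UnitModel] = []
    for model in (UnitModel.DOMINANT, UnitModel.RECESSIVE_HOM,
                  UnitModel.RECESSIVE_COMPHET, UnitModel.XLINKED):
        if model not in scanned or _MODE_FOR_MODEL[model] not in modes:
            continue
        if model is UnitModel.DOMINANT and n_het >= 1:
            out.append(model)
        elif model is UnitModel.RECESSIVE_HOM and \
                Zygosity.HOM_ALT in zygosities:
            out.append(model)
        elif model is UnitModel.RECESSIVE_COMPHET and n_het >= 2:
            out.append(model)
        elif model is UnitModel.XLINKED and any(
                z in (Zygosity.HEMIZYGOUS, Zygosity.HOM_ALT, Zygosity.HET)
                for z in zygosities):
            out.append(model)
    return out


def _sequenced_parents(
    family: Family, proband: Individual,
) -> tuple[Individual | None, Individual | None]:
    father = family.member(proband.father_id) if proband.father_id else None
    mother = family.member(proband.mother_id) if proband.mother_id else None
    if father is not None and not father.sequenced:
        father = None
    if mother is not None and not mother.sequenced:
        mother = None
    return father, mother


def scan_compound_het(
    family: Family,
    gene: str,
    het_variants: list[VariantRecord],
) -> list[CandidateUnit]:
    """Enumerate trans-compatible heterozygous pairs in one gene.

    A pair is rejected as cis when any single sequenced parent carries both
    alleles.  Phase is ``trans_confirmed`` when the father carries exactly
    one allele and the mother exactly the other, or when an unaffected
    sequenced direct relative carries exactly one of the two; otherwise
    ``phase_unknown`` (singleton probands).  With more than two candidate
    alleles, all surviving pairs are returned ranked by their count of
    truncating alleles, then by the lower of the pair's maximum reference
    MAFs.
    """
    proband = primary_proband(family)
    hets = [
        v for v in het_variants
        if family.genotype(proband.sample_id, v.key) is Zygosity.HET
    ]
    if len(set(v.key for v in hets)) < 2:
        return []
    father, mother = _sequenced_parents(family, proband)
    relatives = [
        m for m in family.members
        if m.sample_id != proband.sample_id and m.sequenced
        and m.affected is Affection.UNAFFECTED
    ]

    units: list[CandidateUnit] = []
    seen: set[frozenset[VariantKey]] = set()
    for v1, v2 in combinations(hets, 2):
        pair = frozenset((v1.key, v2.key))
        if len(pair) != 2 or pair in seen:
            continue
        seen.add(pair)

        def carried(member: Individual, key: VariantKey) -> bool:
            return family.genotype(member.sample_id, key).carries_alt

        cis = any(
            carried(parent, v1.key) and carried(parent, v2.key)
            for parent in (father, mother) if parent is not None
        )
        if cis:
            continue
        phase = Phase.PHASE_UNKNOWN
        if father is not None and mother is not None:
            f1, f2 = carried(father, v1.key), carried(father, v2.key)
            m1, m2 = carried(mother, v1.key), carried(mother, v2.key)
            if (f1 and not f2 and m2 and not m1) or \
                    (f2 and not f1 and m1 and not m2):
                phase = Phase.TRANS_CONFIRMED
        if phase is not Phase.TRANS_CONFIRMED:
            for rel in relatives:
                if carried(rel, v1.key) != carried(rel, v2.key):
                    phase = Phase.TRANS_CONFIRMED
                    break
        units.append(CandidateUnit(
            family_id=family.family_id, gene=gene,
            model=UnitModel.RECESSIVE_COMPHET,
            variants=tuple(sorted(pair)),
            phase=phase,
        ))

    by_key = {v.key: v for v in hets}

    def rank(unit: CandidateUnit) -> tuple[int, float]:
        n_trunc = sum(
            1 for k in unit.variants
            if by_key[k].consequence in TRUNCATING_LIKE
        )
        worst_maf = min(
            max_reference_maf(by_key[k])[0] for k in unit.variants
        )
        return (-n_trunc, worst_maf)

    units.sort(key=rank)
    return units


def detect_de_novo(family: Family, variant: VariantRecord) -> DeNovoStatus:
    """De novo iff the proband carries the allele and both sequenced
    biological parents are homozygous reference.

    A missing or unsequenced parent makes the call untestable — except
    that a single typed parent already carrying the allele refutes de novo
    outright (inherited).
    """
    proband = primary_proband(family)
    if not family.genotype(proband.sample_id, variant.key).carries_alt:
        return DeNovoStatus.UNTESTABLE
    father, mother = _sequenced_parents(family, proband)
    calls = []
    for parent in (father, mother):
        if parent is None:
            calls.append(None)
            continue
        z = family.genotype(parent.sample_id, variant.key)
        calls.append(None if z is Zygosity.MISSING else z)
    if any(c is not None and c.carries_alt for c in calls):
        return DeNovoStatus.INHERITED
    if any(c is None for c in calls):
        return DeNovoStatus.UNTESTABLE
    return DeNovoStatus.DE_NOVO


def _carries_full_genotype(
    family: Family, member: Individual, unit: CandidateUnit,
) -> bool:
    if unit.model is UnitModel.RECESSIVE_HOM:
        return family.genotype(member.sample_id, unit.variants[0]) in (
            Zygosity.HOM_ALT, Zygosity.HEMIZYGOUS)
    if unit.model is UnitModel.RECESSIVE_COMPHET:
        return all(
            family.genotype(member.sample_id, k).carries_alt
            for k in unit.variants
        )
    if unit.model is UnitModel.XLINKED:
        z = family.genotype(member.sample_id, unit.variants[0])
        if member.sex is Sex.MALE:
            return z.carries_alt
        return z in (Zygosity.HOM_ALT,)
    # dominant: carrying the het allele at all is the causal genotype
    return family.genotype(member.sample_id, unit.variants[0]).carries_alt


def check_segregation(family: Family, unit: CandidateUnit) -> Segregation:
    """Refute a unit when an unaffected sequenced relative carries the full
    causal genotype; unaffected carriers of half a recessive unit are
    consistent.  Relatives of unknown affection status can neither confirm
    nor violate.
    """
    proband = primary_proband(family)
    informative = False
    for member in family.members:
        if member.sample_id == proband.sample_id or not member.sequenced:
            continue
        typed = any(
            family.genotype(member.sample_id, k) is not Zygosity.MISSING
            for k in unit.variants
        )
        if not typed:
            continue
        if member.affected is not Affection.UNAFFECTED:
            continue
        informative = True
        if _carries_full_genotype(family, member, unit):
            return Segregation.VIOLATED
    return Segregation.CONSISTENT if informative else Segregation.UNTESTED


def scan_xlinked(
    family: Family,
    gene: str,
    variants: list[VariantRecord],
) -> list[CandidateUnit]:
    """X-linked units: hemizygous affected males; affected females
    homozygous (or heterozygous, flagged low-confidence)."""
    proband = primary_proband(family)
    units: list[CandidateUnit] = []
    for v in variants:
        z = family.genotype(proband.sample_id, v.key)
        if proband.sex is not Sex.FEMALE:
            # male or unknown-sex proband: require a hemizygous call
            if z is Zygosity.HEMIZYGOUS:
                units.append(CandidateUnit(
                    family_id=family.family_id, gene=gene,
                    model=UnitModel.XLINKED, variants=(v.key,),
                ))
        else:
            if z is Zygosity.HOM_ALT:
                units.append(CandidateUnit(
                    family_id=family.family_id, gene=gene,
                    model=UnitModel.XLINKED, variants=(v.key,),
                ))
            elif z is Zygosity.HET:
                units.append(CandidateUnit(
                    family_id=family.family_id, gene=gene,
                    model=UnitModel.XLINKED, variants=(v.key,),
                    low_confidence=True,
                ))
    return units


def unit_predictor_exclusion(
    unit: CandidateUnit, by_key: dict[VariantKey, VariantRecord],
) -> bool:
    """Pair-aware step-4 rule: exclude a single-variant unit whose missense
    allele is triple-benign; exclude a two-variant unit only when BOTH
    alleles are triple-benign."""
    verdicts = [triple_benign(by_key[k].predictions) for k in unit.variants]
    return all(verdicts)


def flag_digenic(
    family: Family, units: list[CandidateUnit],
) -> list[tuple[CandidateUnit, CandidateUnit]]:
    """Advisory digenic pairings over surviving monoallelic dominant units
    in different genes.  Never suppresses the individual units."""
    dominants = [u for u in units if u.model is UnitModel.DOMINANT]
    pairs = []
    for u1, u2 in combinations(dominants, 2):
        if u1.gene != u2.gene:
            pairs.append((u1, u2))
    return pairs


def build_units(
    family: Family,
    retained: list[VariantRecord],
    panel: GenePanel,
    policy: FilterPolicy,
) -> list[CandidateUnit]:
    """Form, predictor-screen and segregation-check all candidate units for
    one family from its cascade-retained variants.

    Within a (family, gene), a formed recessive explanation (homozygous or
    compound-het) suppresses single-het dominant hypotheses for the same
    gene: two qualifying hits in a recessive-capable gene are the stronger
    hypothesis.  Dominant units in sporadic families re-impose the
    dominant zero-frequency rule on their allele.  Units violating
    segregation are dropped here and never reach reports.
    """
    proband = primary_proband(family)
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in retained:
        if v.key[0] in panel:
            by_gene.setdefault(v.key[0], []).append(v)

    units: list[CandidateUnit] = []
    for gene, variants in by_gene.items():
        by_key = {v.key: v for v in variants}
        models = match_inheritance(family, gene, variants, panel)
        gene_units: list[CandidateUnit] = []

        if UnitModel.RECESSIVE_HOM in models:
            for v in variants:
                if family.genotype(proband.sample_id, v.key) is \
                        Zygosity.HOM_ALT:
                    gene_units.append(CandidateUnit(
                        family_id=family.family_id, gene=gene,
                        model=UnitModel.RECESSIVE_HOM, variants=(v.key,),
                    ))
        if UnitModel.RECESSIVE_COMPHET in models:
            gene_units.extend(scan_compound_het(family, gene, variants))
        if UnitModel.XLINKED in models:
            gene_units.extend(scan_xlinked(family, gene, variants))
        recessive_explained = any(
            u.model in (UnitModel.RECESSIVE_HOM, UnitModel.RECESSIVE_COMPHET)
            for u in gene_units
        )
        if UnitModel.DOMINANT in models and not recessive_explained:
            for v in variants:
                if family.genotype(proband.sample_id, v.key) is not \
                        Zygosity.HET:
                    continue
                if family.declared_model is InheritanceModel.SPORADIC:
                    maf, _ = max_reference_maf(v, policy.frequency_sources)
                    if maf > policy.maf_dominant:
                        continue
                unit = CandidateUnit(
                    family_id=family.family_id, gene=gene,
                    model=UnitModel.DOMINANT, variants=(v.key,),
                )
                unit.de_novo = detect_de_novo(family, v)
                gene_units.append(unit)

        for unit in gene_units:
            if unit_predictor_exclusion(unit, by_key):
                continue
            unit.segregation = check_segregation(family, unit)
            if unit.segregation is Segregation.VIOLATED:
                continue
            if unit.model is UnitModel.DOMINANT and \
                    unit.de_novo is DeNovoStatus.UNTESTABLE:
                unit.de_novo = detect_de_novo(family, by_key[unit.variants[0]])
            units.append(unit)
    return units
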