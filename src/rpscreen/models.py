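"""Core domain types for family-based exome variant prioritization.

The central objects are :class:`VariantRecord` (one normalized alternate
allele with its functional annotation, in-silico predictor verdicts and
reference-population allele counts), :class:`Family` (a pedigree plus
per-sample zygosity calls), and :class:`CandidateUnit` (a prioritized causal
hypothesis — one or two variants in one gene under a specific inheritance
model — for one family).

Variants are identified throughout by the key ``(gene, hgvs_c)``: the
annotated-table dialect used for the bundled study tables omits genomic
coordinates, and cDNA-level change strings within a gene are unique in
practice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Consequence(str, enum.Enum):
    """Closed vocabulary of functional consequence classes."""

    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    NONFRAMESHIFT_DELETION = "nonframeshift_deletion"
    NONFRAMESHIFT_INSERTION = "nonframeshift_insertion"
    SPLICING = "splicing"
    SPLICE_ACCEPTOR_REGION = "splice_acceptor_region"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: Consequence classes that touch a splice site; they survive the
#: noncoding/synonymous exclusions regardless of coding status.
SPLICE_ALTERING = frozenset(
    {Consequence.SPLICING, Consequence.SPLICE_ACCEPTOR_REGION}
)

#: Consequence classes for which missense predictors are meaningful.
MISSENSE = frozenset({Consequence.NONSYNONYMOUS})


class ProveanCall(str, enum.Enum):
    DELETERIOUS = "Deleterious"
    NEUTRAL = "Neutral"
    MISSING = "missing"


class SiftCall(str, enum.Enum):
    DAMAGING = "Damaging"
    TOLERATED = "Tolerated"
    MISSING = "missing"


class PolyphenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


@dataclass(frozen=True)
class PredictionTriple:
    """Categorical verdicts from the three in-silico missense predictors.

    Truncating and splicing variants normally carry all-missing verdicts:
    the predictors only score amino-acid substitutions.
    """

    provean: ProveanCall = ProveanCall.MISSING
    sift: SiftCall = SiftCall.MISSING
    polyphen: PolyphenCall = PolyphenCall.MISSING


VariantKey = tuple[str, str]  # (gene symbol, normalized hgvs_c)


@dataclass
class VariantRecord:
    """One alternate allele with annotation, predictions and frequencies.

    ``frequencies`` maps a reference-population source name to an
    ``(allele_count, allele_number)`` pair; absence from a source is
    equivalent to a (0, 0) entry.
    """

    gene: str
    hgvs_c: str
    chrom: str = ""
    pos: int = 1
    ref: str = ""
    alt: str = ""
    transcript: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.NONSYNONYMOUS
    predictions: PredictionTriple = field(default_factory=PredictionTriple)
    frequencies: dict[str, tuple[int, int]] = field(default_factory=dict)
    quality: float | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for source, (ac, an) in self.frequencies.items():
            if ac < 0 or an < 0:
                raise ValueError(f"negative allele count for {source}")
            if ac > an:
                raise ValueError(
                    f"allele_count {ac} > allele_number {an} for {source}"
                )

    @property
    def key(self) -> VariantKey:
        return (self.gene, self.hgvs_c)


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMIZYGOUS = "hemizygous"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMIZYGOUS)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(str, enum.Enum):
    """Declared family-level inheritance class (cohort stratification)."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    SPORADIC = "sporadic"
    XLINKED = "xlinked"


class Mode(str, enum.Enum):
    """Per-gene permitted inheritance modes, as cataloged in gene panels."""

    AD = "ad"
    AR = "ar"
    XL = "xl"


@dataclass
class Individual:
    sample_id: str
    family_id: str
    father_id: str = ""
    mother_id: str = ""
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    sequenced: bool = True


@dataclass
class Family:
    """A pedigree with per-sample zygosity calls keyed by variant.

    ``genotypes`` maps ``(sample_id, (gene, hgvs_c))`` to a
    :class:`Zygosity`; samples missing a key are treated as
    :attr:`Zygosity.MISSING` for untyped sites and as ``hom_ref`` only when
    explicitly recorded.
    """

    family_id: str
    members: list[Individual]
    declared_model: InheritanceModel
    genotypes: dict[tuple[str, VariantKey], Zygosity] = field(
        default_factory=dict
    )

    def member(self, sample_id: str) -> Individual | None:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        return None

    @property
    def probands(self) -> list[Individual]:
        return [
            m for m in self.members
            if m.affected is Affection.AFFECTED and m.sequenced
        ]

    def genotype(self, sample_id: str, key: VariantKey) -> Zygosity:
        return self.genotypes.get((sample_id, key), Zygosity.MISSING)

    def validate(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicated sample id in family {self.family_id}")
        if not self.probands:
            raise ValueError(
                f"family {self.family_id} has no affected, sequenced member"
            )
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for parent_id, want_sex, label in (
                (m.father_id, Sex.MALE, "father"),
                (m.mother_id, Sex.FEMALE, "mother"),
            ):
                if parent_id and parent_id in by_id:
                    parent = by_id[parent_id]
                    if parent.sex not in (want_sex, Sex.UNKNOWN):
                        raise ValueError(
                            f"{label} {parent_id} of {m.sample_id} has "
                            f"sex {parent.sex.value}"
                        )
        # no individual may be its own ancestor
        for m in self.members:
            seen: set[str] = set()
            stack = [p for p in (m.father_id, m.mother_id) if p]
            while stack:
                cur = stack.pop()
                if cur == m.sample_id:
                    raise ValueError(
                        f"{m.sample_id} is its own ancestor in "
                        f"family {self.family_id}"
                    )
                if cur in seen or cur not in by_id:
                    continue
                seen.add(cur)
                anc = by_id[cur]
                stack.extend(p for p in (anc.father_id, anc.mother_id) if p)


@dataclass
class GenePanel:
    """Gene symbol -> permitted inheritance modes (non-empty)."""

    name: str
    entries: dict[str, frozenset[Mode]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"panel {self.name!r} is empty")
        for gene, modes in self.entries.items():
            if not modes:
                raise ValueError(f"panel gene {gene} has no modes")

    def modes(self, gene: str) -> frozenset[Mode]:
        return self.entries.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


@dataclass
class KnownMutationCatalog:
    """Exact-lookup catalog of literature-reported mutations."""

    entries: dict[VariantKey, str] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def tag(self, key: VariantKey) -> str:
        return self.entries.get(key, "")


class UnitModel(str, enum.Enum):
    """Inheritance hypothesis attached to a candidate unit."""

    DOMINANT = "dominant"
    RECESSIVE_HOM = "recessive_hom"
    RECESSIVE_COMPHET = "recessive_comphet"
    XLINKED = "xlinked"


class Phase(str, enum.Enum):
    TRANS_CONFIRMED = "trans_confirmed"
    PHASE_UNKNOWN = "phase_unknown"
    NOT_APPLICABLE = "not_applicable"


class Segregation(str, enum.Enum):
    CONSISTENT = "consistent"
    VIOLATED = "violated"
    UNTESTED = "untested"


class DeNovoStatus(str, enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNTESTABLE = "untestable"


class Novelty(str, enum.Enum):
    NOVEL = "novel"
    REPORTED = "reported"


class Tier(str, enum.Enum):
    KNOWN_RP_GENE = "known_rp_gene"
    UNCERTAIN_CANDIDATE = "uncertain_candidate"
    OTHER_RETINOPATHY_GENE = "other_retinopathy_gene"
    UNSOLVED = "unsolved"


@dataclass
class CandidateUnit:
    """A prioritized causal hypothesis for one family.

    One variant for dominant / homozygous-recessive / X-linked units, two
    distinct variants for a compound heterozygote.
    """

    family_id: str
    gene: str
    model: UnitModel
    variants: tuple[VariantKey, ...]
    phase: Phase = Phase.NOT_APPLICABLE
    de_novo: DeNovoStatus = DeNovoStatus.UNTESTABLE
    segregation: Segregation = Segregation.UNTESTED
    novelty: dict[VariantKey, Novelty] = field(default_factory=dict)
    tier: Tier | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.model is UnitModel.RECESSIVE_COMPHET:
            if len(set(self.variants)) != 2:
                raise ValueError(
                    "compound-het unit needs exactly 2 distinct variants"
                )
        elif len(self.variants) != 1:
            raise ValueError(
                f"{self.model.value} unit needs exactly 1 variant"
            )

    @property
    def identity(self) -> tuple[str, str, str, frozenset[VariantKey]]:
        """Exact-match identity used for simulator recovery scoring."""
        return (self.family_id, self.gene, self.model.value,
                frozenset(self.variants))
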