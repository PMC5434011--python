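"""Synthetic family-cohort generator with a ground-truth manifest.

Emulates the study design the pipeline targets: a cohort of small
families (trio to three-generation) declared dominant / recessive /
sporadic / X-linked, each optionally carrying one implanted causal unit
that satisfies every filter and segregation rule by construction, plus
decoy variants each engineered to fail exactly one named rule:

==============  =====================================================
decoy rule      construction
==============  =====================================================
qc              call quality below the Q30 gate
frequency       reference MAF far above the recessive threshold
consequence     synonymous or noncoding, not splice-altering
predictor       missense called benign by all three predictors
segregation     causal-style genotype shared by an unaffected relative
comphet_cis     two heterozygous alleles inherited from one parent
==============  =====================================================

Because every non-causal variant fails at least one rule by
construction, a noise-free run must recover every implanted unit
(sensitivity 1.0) with zero decoy leaks; :func:`evaluate_recovery`
scores exactly that against the manifest.  Positions live on synthetic
contigs (one per gene; X-linked genes on ``chrX``) — no reference genome
is required.  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

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
    PolyphenCall,
    PredictionTriple,
    ProveanCall,
    Sex,
    SiftCall,
    UnitModel,
    VariantKey,
    VariantRecord,
    Zygosity,
)

DECOY_RULES = ("qc", "frequency", "consequence", "predictor",
               "segregation", "comphet_cis")

#: In-house control cohort of 2020 unrelated individuals -> 4040 alleles.
IN_HOUSE_AN = 4040
EXAC_AN = 121412

DAMAGING = PredictionTriple(
    ProveanCall.DELETERIOUS, SiftCall.DAMAGING, PolyphenCall.PROBABLY_DAMAGING
)
BENIGN = PredictionTriple(
    ProveanCall.NEUTRAL, SiftCall.TOLERATED, PolyphenCall.BENIGN
)
MISSING = PredictionTriple()


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Family counts and per-stratum causal fractions default to the cohort
    composition and diagnostic yields of the study design being emulated
    (22/19/52/5 families; yields 0.59/0.42/0.31/0.80).  ``seed`` fully
    determines the output.
    """

    seed: int = 0
    n_dominant: int = 22
    n_recessive: int = 19
    n_sporadic: int = 52
    n_xlinked: int = 5
    causal_fraction_dominant: float = 0.59
    causal_fraction_recessive: float = 0.42
    causal_fraction_sporadic: float = 0.31
    causal_fraction_xlinked: float = 0.80
    background_mean: float = 150.0
    predictor_false_benign: float = 0.0
    missing_parent_prob: float = 0.7
    #: Sporadic causal mechanism mix (comphet / homozygous / de novo het),
    #: mirroring the 12:2:2 split among solved sporadic probands.
    sporadic_mix: tuple[float, float, float] = (0.75, 0.125, 0.125)

    def __post_init__(self) -> None:
        for name in ("causal_fraction_dominant", "causal_fraction_recessive",
                     "causal_fraction_sporadic", "causal_fraction_xlinked",
                     "predictor_false_benign", "missing_parent_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_dominant + self.n_recessive + self.n_sporadic + \
                self.n_xlinked <= 0:
            raise ValueError("empty cohort refused: all family counts zero")
        if abs(sum(self.sporadic_mix) - 1.0) > 1e-9:
            raise ValueError("sporadic_mix must sum to 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sporadic_mix" in raw:
            raw["sporadic_mix"] = tuple(raw["sporadic_mix"])
        return cls(**raw)


@dataclass
class DecoyRecord:
    family_id: str
    key: VariantKey
    rule: str  # first rule this decoy must fail


@dataclass
class TruthManifest:
    """Simulator ground truth for recovery scoring."""

    cohort_id: str
    implanted: dict[str, CandidateUnit | None] = field(default_factory=dict)
    decoys: list[DecoyRecord] = field(default_factory=list)

    def implanted_units(self) -> list[CandidateUnit]:
        return [u for u in self.implanted.values() if u is not None]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cohort_id": self.cohort_id,
            "implanted": {
                fid: None if unit is None else {
                    "gene": unit.gene, "model": unit.model.value,
                    "variants": [list(k) for k in unit.variants],
                }
                for fid, unit in self.implanted.items()
            },
            "decoys": [
                {"family": d.family_id, "gene": d.key[0],
                 "hgvs_c": d.key[1], "rule": d.rule}
                for d in self.decoys
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        manifest = cls(cohort_id=raw["cohort_id"])
        for fid, entry in raw["implanted"].items():
            if entry is None:
                manifest.implanted[fid] = None
            else:
                variants = tuple(tuple(k) for k in entry["variants"])
                manifest.implanted[fid] = CandidateUnit(
                    family_id=fid, gene=entry["gene"],
                    model=UnitModel(entry["model"]), variants=variants,
                )
        manifest.decoys = [
            DecoyRecord(d["family"], (d["gene"], d["hgvs_c"]), d["rule"])
            for d in raw["decoys"]
        ]
        return manifest


class _VariantFactory:
    """Deterministic synthetic variants: one contig per gene, increasing
    positions, globally unique cDNA tokens."""

    def __init__(self, panel: GenePanel) -> None:
        self._counter = 0
        self._gene_pos: dict[str, int] = {}
        self._contigs: dict[str, str] = {}
        for i, gene in enumerate(sorted(panel.entries), 1):
            if Mode.XL in panel.modes(gene):
                self._contigs[gene] = "chrX"
            else:
                self._contigs[gene] = f"chrS{i}"

    def make(
        self,
        gene: str,
        consequence: Consequence,
        predictions: PredictionTriple,
        ac_in_house: int = 0,
        quality: float = 60.0,
        depth: int = 50,
    ) -> VariantRecord:
        self._counter += 1
        pos = self._gene_pos.get(gene, 1000) + 20
        self._gene_pos[gene] = pos
        return VariantRecord(
            gene=gene,
            hgvs_c=f"c.{self._counter}A>G",
            hgvs_p=f"p.Syn{self._counter}" if
            consequence is Consequence.NONSYNONYMOUS else "",
            chrom=self._contigs[gene],
            pos=pos, ref="A", alt="G",
            consequence=consequence,
            predictions=predictions,
            frequencies={
                "in_house": (ac_in_house, IN_HOUSE_AN),
                "exac": (0, EXAC_AN),
            },
            quality=quality, depth=depth,
        )


def _noisy_damaging(rng: random.Random, rate: float) -> PredictionTriple:
    """Causal-missense verdicts with independent per-predictor
    false-benign flips at the given rate."""
    return PredictionTriple(
        provean=ProveanCall.NEUTRAL if rng.random() < rate
        else ProveanCall.DELETERIOUS,
        sift=SiftCall.TOLERATED if rng.random() < rate
        else SiftCall.DAMAGING,
        polyphen=PolyphenCall.BENIGN if rng.random() < rate
        else PolyphenCall.PROBABLY_DAMAGING,
    )


@dataclass
class _FamilyBuild:
    family: Family
    variants: list[VariantRecord] = field(default_factory=list)

    def set_gt(self, sample_id: str, variant: VariantRecord,
               zygosity: Zygosity) -> None:
        self.family.genotypes[(sample_id, variant.key)] = zygosity

    def add(self, variant: VariantRecord,
            calls: dict[str, Zygosity]) -> None:
        self.variants.append(variant)
        for member in self.family.members:
            z = calls.get(member.sample_id, Zygosity.HOM_REF)
            self.set_gt(member.sample_id, variant, z)


def _make_pedigree(
    family_id: str, model: InheritanceModel, template: str,
    proband_sex: Sex, affected_father: bool = False,
) -> Family:
    members: list[Individual] = []
    if template == "singleton":
        members.append(Individual(
            sample_id=f"{family_id}_p", family_id=family_id,
            sex=proband_sex, affected=Affection.AFFECTED))
    else:
        father = Individual(
            sample_id=f"{family_id}_f", family_id=family_id, sex=Sex.MALE,
            affected=Affection.AFFECTED if affected_father
            else Affection.UNAFFECTED)
        mother = Individual(
            sample_id=f"{family_id}_m", family_id=family_id, sex=Sex.FEMALE,
            affected=Affection.UNAFFECTED)
        child = Individual(
            sample_id=f"{family_id}_p", family_id=family_id,
            father_id=father.sample_id, mother_id=mother.sample_id,
            sex=proband_sex, affected=Affection.AFFECTED)
        members = [child, father, mother]
        if template == "quartet":
            members.append(Individual(
                sample_id=f"{family_id}_s", family_id=family_id,
                father_id=father.sample_id, mother_id=mother.sample_id,
                sex=Sex.FEMALE, affected=Affection.UNAFFECTED))
        elif template == "three_gen":
            grandfather = Individual(
                sample_id=f"{family_id}_gf", family_id=family_id,
                sex=Sex.MALE, affected=Affection.AFFECTED)
            grandmother = Individual(
                sample_id=f"{family_id}_gm", family_id=family_id,
                sex=Sex.FEMALE, affected=Affection.UNAFFECTED)
            father.father_id = grandfather.sample_id
            father.mother_id = grandmother.sample_id
            members.extend([grandfather, grandmother])
    family = Family(family_id=family_id, members=members,
                    declared_model=model)
    return family


def _proband(build: _FamilyBuild) -> Individual:
    return build.family.member(f"{build.family.family_id}_p")


def _propagate_carrier(
    family: Family, calls: dict[str, Zygosity], carrier_id: str,
    rng: random.Random,
) -> None:
    """Keep carrier calls Mendelian up the pedigree: any carrier whose
    parents are in the family must have a carrier parent too."""
    member = family.member(carrier_id)
    while member is not None and member.father_id and member.mother_id \
            and family.member(member.father_id) is not None:
        parents = [member.father_id, member.mother_id]
        if any(calls.get(p, Zygosity.HOM_REF).carries_alt for p in parents):
            break
        chosen = rng.choice(parents)
        calls[chosen] = Zygosity.HET
        member = family.member(chosen)


def _implant_causal(
    build: _FamilyBuild, rng: random.Random, factory: _VariantFactory,
    panel: GenePanel, config: SimulationConfig, mechanism: str, gene: str,
) -> CandidateUnit:
    fam = build.family
    fid = fam.family_id
    proband = _proband(build)
    father, mother = f"{fid}_f", f"{fid}_m"
    has_parents = fam.member(father) is not None

    def causal_variant(truncating_ok: bool = True) -> VariantRecord:
        if truncating_ok and rng.random() < 0.4:
            return factory.make(gene, Consequence.STOPGAIN, MISSING)
        return factory.make(
            gene, Consequence.NONSYNONYMOUS,
            _noisy_damaging(rng, config.predictor_false_benign))

    if mechanism == "dominant_transmitted":
        v = causal_variant()
        calls = {proband.sample_id: Zygosity.HET, father: Zygosity.HET}
        if fam.member(f"{fid}_gf") is not None:
            calls[f"{fid}_gf"] = Zygosity.HET
        build.add(v, calls)
        return CandidateUnit(fid, gene, UnitModel.DOMINANT, (v.key,))
    if mechanism == "de_novo":
        v = causal_variant()
        build.add(v, {proband.sample_id: Zygosity.HET})
        return CandidateUnit(fid, gene, UnitModel.DOMINANT, (v.key,),
                             de_novo=DeNovoStatus.DE_NOVO)
    if mechanism == "recessive_hom":
        v = causal_variant()
        calls = {proband.sample_id: Zygosity.HOM_ALT}
        if has_parents:
            calls[father] = Zygosity.HET
            calls[mother] = Zygosity.HET
        sib = fam.member(f"{fid}_s")
        if sib is not None:
            calls[sib.sample_id] = rng.choice(
                [Zygosity.HOM_REF, Zygosity.HET])
        build.add(v, calls)
        return CandidateUnit(fid, gene, UnitModel.RECESSIVE_HOM, (v.key,))
    if mechanism == "comphet":
        v1, v2 = causal_variant(), causal_variant()
        calls1 = {proband.sample_id: Zygosity.HET}
        calls2 = {proband.sample_id: Zygosity.HET}
        if has_parents:
            calls1[father] = Zygosity.HET  # paternal allele
            calls2[mother] = Zygosity.HET  # maternal allele
        sib = fam.member(f"{fid}_s")
        if sib is not None:
            # unaffected sib inherits at most one of the two alleles
            which = rng.choice(["none", "v1", "v2"])
            if which == "v1":
                calls1[sib.sample_id] = Zygosity.HET
            elif which == "v2":
                calls2[sib.sample_id] = Zygosity.HET
        build.add(v1, calls1)
        build.add(v2, calls2)
        return CandidateUnit(
            fid, gene, UnitModel.RECESSIVE_COMPHET,
            tuple(sorted((v1.key, v2.key))),
            phase=Phase.TRANS_CONFIRMED if has_parents
            else Phase.PHASE_UNKNOWN)
    if mechanism == "xlinked":
        v = causal_variant()
        calls = {proband.sample_id: Zygosity.HEMIZYGOUS}
        if has_parents:
            calls[mother] = Zygosity.HET  # carrier mother
            calls[father] = Zygosity.HOM_REF
        build.add(v, calls)
        return CandidateUnit(fid, gene, UnitModel.XLINKED, (v.key,))
    raise ValueError(f"unknown causal mechanism {mechanism!r}")


def _implant_decoys(
    build: _FamilyBuild, rng: random.Random, factory: _VariantFactory,
    genes: dict[str, list[str]], reserved: set[str],
    manifest: TruthManifest,
) -> None:
    """One decoy per rule class feasible for this family's pedigree.

    ``reserved`` tracks genes already hosting rare damaging heterozygous
    survivors for this family (the causal gene on entry); each new
    damaging-het decoy claims its gene there.  This keeps any recessive-
    capable gene from accumulating an unintended trans-compatible pair,
    which is what guarantees zero leaks on noise-free cohorts.
    """
    fam = build.family
    fid = fam.family_id
    proband = _proband(build)
    has_parents = fam.member(f"{fid}_f") is not None

    benign_genes: set[str] = set()

    def pick(pool: list[str], reserve: bool = False) -> str:
        # damaging-het decoys also avoid benign-het genes: a mixed
        # benign/damaging het pair would survive the pair-level rule
        excluded = reserved | (benign_genes if reserve else set())
        choices = [g for g in pool if g not in excluded]
        gene = rng.choice(choices)
        if reserve:
            reserved.add(gene)
        return gene

    def het_with_carrier_parent(v: VariantRecord) -> dict[str, Zygosity]:
        calls = {proband.sample_id: Zygosity.HET}
        if has_parents:
            carrier = rng.choice([f"{fid}_f", f"{fid}_m"])
            calls[carrier] = Zygosity.HET
            _propagate_carrier(fam, calls, carrier, rng)
        return calls

    autosomal = genes["autosomal"]

    # qc and frequency decoys never reach the engine, so their genes are
    # free to re-use; consequence/predictor decoys likewise can share.
    v = factory.make(pick(autosomal), Consequence.NONSYNONYMOUS, DAMAGING,
                     quality=10.0)
    build.add(v, het_with_carrier_parent(v))
    manifest.decoys.append(DecoyRecord(fid, v.key, "qc"))

    v = factory.make(pick(autosomal), Consequence.NONSYNONYMOUS, DAMAGING,
                     ac_in_house=100 + rng.randrange(300))
    build.add(v, het_with_carrier_parent(v))
    manifest.decoys.append(DecoyRecord(fid, v.key, "frequency"))

    csq = rng.choice([Consequence.SYNONYMOUS, Consequence.NONCODING])
    v = factory.make(pick(autosomal), csq, MISSING)
    build.add(v, het_with_carrier_parent(v))
    manifest.decoys.append(DecoyRecord(fid, v.key, "consequence"))

    benign_gene = pick(genes["ad_autosomal"])
    benign_genes.add(benign_gene)
    v = factory.make(benign_gene, Consequence.NONSYNONYMOUS, BENIGN)
    build.add(v, het_with_carrier_parent(v))
    manifest.decoys.append(DecoyRecord(fid, v.key, "predictor"))

    # segregation violator: the full causal-style genotype shared by an
    # unaffected sequenced relative — needs such a relative
    unaffected = [
        m for m in fam.members
        if m.sample_id != proband.sample_id
        and m.affected is Affection.UNAFFECTED and m.sequenced
    ]
    if unaffected:
        if fam.declared_model is InheritanceModel.XLINKED:
            gene = pick(genes["xl"], reserve=True)
            v = factory.make(gene, Consequence.NONSYNONYMOUS, DAMAGING)
            build.add(v, {proband.sample_id: Zygosity.HEMIZYGOUS,
                          f"{fid}_f": Zygosity.HEMIZYGOUS,  # the violator
                          f"{fid}_m": Zygosity.HET})
        elif fam.declared_model is InheritanceModel.RECESSIVE:
            gene = pick(genes["ar_autosomal"], reserve=True)
            v = factory.make(gene, Consequence.NONSYNONYMOUS, DAMAGING)
            calls = {proband.sample_id: Zygosity.HOM_ALT,
                     f"{fid}_f": Zygosity.HET, f"{fid}_m": Zygosity.HET}
            sib = fam.member(f"{fid}_s")
            if sib is not None:
                calls[sib.sample_id] = Zygosity.HOM_ALT  # the violator
            else:
                calls[f"{fid}_f"] = Zygosity.HOM_ALT
            build.add(v, calls)
        else:
            gene = pick(genes["ad_autosomal"], reserve=True)
            v = factory.make(gene, Consequence.NONSYNONYMOUS, DAMAGING)
            # violator must be a parent so the call stays Mendelian
            unaffected_parents = [
                m.sample_id for m in unaffected
                if m.sample_id in (f"{fid}_f", f"{fid}_m")
            ]
            violator = rng.choice(unaffected_parents or
                                  [m.sample_id for m in unaffected])
            calls = {proband.sample_id: Zygosity.HET, violator: Zygosity.HET}
            build.add(v, calls)
        manifest.decoys.append(DecoyRecord(fid, v.key, "segregation"))

    # cis pair: both alleles on one parental haplotype; needs parents and
    # a recessive-only gene so no dominant hypothesis can pick them up
    if has_parents and fam.declared_model is not InheritanceModel.XLINKED:
        gene = pick(genes["ar_only_autosomal"], reserve=True)
        parent = rng.choice([f"{fid}_f", f"{fid}_m"])
        for _ in range(2):
            v = factory.make(gene, Consequence.NONSYNONYMOUS, DAMAGING)
            calls = {proband.sample_id: Zygosity.HET, parent: Zygosity.HET}
            _propagate_carrier(fam, calls, parent, rng)
            build.add(v, calls)
            manifest.decoys.append(DecoyRecord(fid, v.key, "comphet_cis"))


def _implant_background(
    build: _FamilyBuild, rng: random.Random, factory: _VariantFactory,
    genes: dict[str, list[str]], reserved: set[str], n: int,
) -> None:
    """Background variation: classed decoys with a frequency spectrum.

    Classes are weighted toward common variation; rare backgrounds are
    synonymous, noncoding or triple-benign so that every background
    variant fails a named rule by construction (see module docstring).
    Rare benign missense placements avoid genes hosting damaging rare
    hets (``reserved``); benign-benign co-occurrence in a gene is safe
    because a double-benign pair is excluded at the unit level.
    """
    fam = build.family
    proband = _proband(build)
    has_parents = fam.member(f"{fam.family_id}_f") is not None
    autosomal = genes["autosomal"]
    benign_pool = [g for g in autosomal if g not in reserved]
    for _ in range(n):
        roll = rng.random()
        if roll < 0.5:
            ac = 50 + int(rng.expovariate(1 / 400.0))
            v = factory.make(rng.choice(autosomal),
                             Consequence.NONSYNONYMOUS, DAMAGING,
                             ac_in_house=min(ac, IN_HOUSE_AN))
        elif roll < 0.7:
            v = factory.make(rng.choice(autosomal), Consequence.SYNONYMOUS,
                             MISSING, ac_in_house=rng.choice([0, 0, 1, 2, 5]))
        elif roll < 0.9:
            v = factory.make(rng.choice(autosomal), Consequence.NONCODING,
                             MISSING, ac_in_house=rng.choice([0, 0, 1, 3]))
        else:
            v = factory.make(rng.choice(benign_pool),
                             Consequence.NONSYNONYMOUS, BENIGN,
                             ac_in_house=rng.choice([0, 0, 1]))
        calls = {proband.sample_id: Zygosity.HET}
        if has_parents:
            carrier = rng.choice(
                [f"{fam.family_id}_f", f"{fam.family_id}_m"])
            calls[carrier] = Zygosity.HET
            _propagate_carrier(fam, calls, carrier, rng)
        build.add(v, calls)


def _gene_pools(panel: GenePanel) -> dict[str, list[str]]:
    pools = {
        "autosomal": [], "ad_autosomal": [], "ar_autosomal": [],
        "ar_only_autosomal": [], "xl": [],
    }
    for gene in sorted(panel.entries):
        modes = panel.modes(gene)
        if Mode.XL in modes:
            pools["xl"].append(gene)
            continue
        pools["autosomal"].append(gene)
        if Mode.AD in modes:
            pools["ad_autosomal"].append(gene)
        if Mode.AR in modes:
            pools["ar_autosomal"].append(gene)
        if modes == frozenset({Mode.AR}):
            pools["ar_only_autosomal"].append(gene)
    for name, pool in pools.items():
        if not pool:
            raise ValueError(f"panel has no genes for pool {name!r}")
    return pools


def simulate_cohort(
    config: SimulationConfig,
    panel: GenePanel | None = None,
) -> tuple[list[Family], dict[str, list[VariantRecord]], TruthManifest]:
    """Generate the cohort: families with genotypes and annotations, plus
    the ground-truth manifest.  Deterministic under ``config.seed``."""
    from .io_formats import load_known_rp_panel

    panel = panel or load_known_rp_panel()
    rng = random.Random(config.seed)
    factory = _VariantFactory(panel)
    genes = _gene_pools(panel)
    manifest = TruthManifest(cohort_id=f"synthetic-seed{config.seed}")

    plan: list[tuple[InheritanceModel, float, str]] = []
    plan += [(InheritanceModel.DOMINANT, config.causal_fraction_dominant,
              f"FAM-D{i:03d}") for i in range(1, config.n_dominant + 1)]
    plan += [(InheritanceModel.RECESSIVE, config.causal_fraction_recessive,
              f"FAM-R{i:03d}") for i in range(1, config.n_recessive + 1)]
    plan += [(InheritanceModel.SPORADIC, config.causal_fraction_sporadic,
              f"FAM-S{i:03d}") for i in range(1, config.n_sporadic + 1)]
    plan += [(InheritanceModel.XLINKED, config.causal_fraction_xlinked,
              f"FAM-X{i:03d}") for i in range(1, config.n_xlinked + 1)]

    families: list[Family] = []
    variants: dict[str, list[VariantRecord]] = {}
    w_comphet, w_hom, _ = config.sporadic_mix
    for model, causal_fraction, fid in plan:
        causal = rng.random() < causal_fraction
        mechanism: str | None = None
        gene: str | None = None
        if model is InheritanceModel.DOMINANT:
            template = rng.choice(["trio", "three_gen"])
            proband_sex = rng.choice([Sex.MALE, Sex.FEMALE])
            affected_father = True
            if causal:
                mechanism = "dominant_transmitted"
                gene = rng.choice(genes["ad_autosomal"])
        elif model is InheritanceModel.RECESSIVE:
            template = "quartet"
            proband_sex = rng.choice([Sex.MALE, Sex.FEMALE])
            affected_father = False
            if causal:
                mechanism = rng.choice(["recessive_hom", "comphet"])
                gene = rng.choice(genes["ar_autosomal"])
        elif model is InheritanceModel.SPORADIC:
            roll = rng.random()
            if causal and roll >= w_comphet + w_hom:
                mechanism = "de_novo"  # needs parents
                template = "trio"
            else:
                template = "singleton" \
                    if rng.random() < config.missing_parent_prob else "trio"
                if causal:
                    mechanism = "comphet" if roll < w_comphet \
                        else "recessive_hom"
            proband_sex = rng.choice([Sex.MALE, Sex.FEMALE])
            affected_father = False
            if causal:
                gene = rng.choice(
                    genes["ad_autosomal"] if mechanism == "de_novo"
                    else genes["ar_autosomal"])
        else:  # X-linked: affected male proband, carrier mother
            template = "trio"
            proband_sex = Sex.MALE
            affected_father = False
            if causal:
                mechanism = "xlinked"
                gene = rng.choice(genes["xl"])

        family = _make_pedigree(fid, model, template, proband_sex,
                                affected_father)
        build = _FamilyBuild(family=family)
        reserved: set[str] = set()
        if causal:
            assert mechanism is not None and gene is not None
            reserved.add(gene)
            manifest.implanted[fid] = _implant_causal(
                build, rng, factory, panel, config, mechanism, gene)
        else:
            manifest.implanted[fid] = None
        _implant_decoys(build, rng, factory, genes, reserved, manifest)
        n_background = max(0, int(rng.gauss(config.background_mean,
                                            config.background_mean / 5)))
        _implant_background(build, rng, factory, genes, reserved,
                            n_background)
        family.validate()
        families.append(family)
        variants[fid] = build.variants
    return families, variants, manifest


# ---------------------------------------------------------------------------
# Recovery scoring

@dataclass
class RecoveryReport:
    n_implanted: int
    n_recovered: int
    false_discoveries: int
    decoy_leaks: dict[str, int]
    missed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float | None:
        """None when nothing was implanted (sensitivity undefined)."""
        if self.n_implanted == 0:
            return None
        return self.n_recovered / self.n_implanted

    @property
    def total_leaks(self) -> int:
        return sum(self.decoy_leaks.values())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_implanted": self.n_implanted,
            "n_recovered": self.n_recovered,
            "sensitivity": self.sensitivity,
            "false_discoveries": self.false_discoveries,
            "decoy_leaks": self.decoy_leaks,
            "missed": [list(m) for m in self.missed],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate_recovery(
    manifest: TruthManifest,
    units: list[CandidateUnit],
    cohort_id: str | None = None,
) -> RecoveryReport:
    """Score pipeline output against the manifest by exact unit identity
    (family, gene, model, variant set)."""
    if cohort_id is not None and cohort_id != manifest.cohort_id:
        raise ValueError(
            f"cohort mismatch: results from {cohort_id!r}, manifest for "
            f"{manifest.cohort_id!r}"
        )
    implanted = {u.identity for u in manifest.implanted_units()}
    emitted = {u.identity for u in units}
    recovered = implanted & emitted
    missed = sorted(
        (fid, gene) for (fid, gene, _, _) in implanted - emitted
    )
    decoy_by_key: dict[tuple[str, VariantKey], str] = {
        (d.family_id, d.key): d.rule for d in manifest.decoys
    }
    leaks = {rule: 0 for rule in DECOY_RULES}
    for unit in units:
        for key in unit.variants:
            rule = decoy_by_key.get((unit.family_id, key))
            if rule is not None:
                leaks[rule] += 1
    return RecoveryReport(
        n_implanted=len(implanted),
        n_recovered=len(recovered),
        false_discoveries=len(emitted - implanted),
        decoy_leaks=leaks,
        missed=missed,
    )


# ---------------------------------------------------------------------------
# Cohort export in the dialects io_formats reads

def zygosity_to_change(family: Family, proband_id: str,
                       variant: VariantRecord,
                       gene_het_count: int) -> str | None:
    z = family.genotype(proband_id, variant.key)
    if z is Zygosity.HOM_ALT:
        return "homozygous"
    if z is Zygosity.HEMIZYGOUS:
        return "hemizygote"
    if z is Zygosity.HET:
        return "compound heterozygous" if gene_het_count >= 2 \
            else "heterozygous"
    return None


def write_cohort(
    families: list[Family],
    variants: dict[str, list[VariantRecord]],
    manifest: TruthManifest,
    out_dir: str | Path,
) -> None:
    """Write the cohort as one PED, one annotated variant table (proband
    genotype configurations), per-family annotated VCFs and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .io_formats import write_ped, write_model_map, write_variant_table

    all_members = [m for fam in families for m in fam.members]
    write_ped(all_members, out / "cohort.ped")
    write_model_map({f.family_id: f.declared_model for f in families},
                    out / "cohort_models.tsv")

    rows = []
    for fam in families:
        proband = fam.probands[0]
        het_counts: dict[str, int] = {}
        for v in variants[fam.family_id]:
            if fam.genotype(proband.sample_id, v.key) is Zygosity.HET:
                het_counts[v.gene] = het_counts.get(v.gene, 0) + 1
        for v in variants[fam.family_id]:
            change = zygosity_to_change(
                fam, proband.sample_id, v, het_counts.get(v.gene, 0))
            if change is None:
                continue
            rows.append((fam.family_id, fam.declared_model, v,
                         change.replace(" ", "_")))
    write_variant_table(rows, out / "cohort_variants.tsv")

    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for fam in families:
        write_family_vcf(fam, variants[fam.family_id],
                         vcf_dir / f"{fam.family_id}.vcf")
    manifest.to_json(out / "manifest.json")


#: INFO keys used by the simulator's VCF export; pass to
#: :func:`rpscreen.io_formats.read_annotated_vcf` as ``frequency_keys``.
VCF_FREQUENCY_KEYS = {
    "in_house": ("AC_INHOUSE", "AN_INHOUSE"),
    "exac": ("AC_EXAC", "AN_EXAC"),
}

_GT_CODE = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.HEMIZYGOUS: "1",
    Zygosity.MISSING: "./.",
}


def write_family_vcf(
    family: Family, variants: list[VariantRecord], path: str | Path,
) -> None:
    """Annotated single-family VCF in the dialect read_annotated_vcf reads."""
    samples = [m.sample_id for m in family.members if m.sequenced]
    contigs = sorted({v.chrom for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    for key, desc in [
        ("GENE", "Gene symbol"), ("CSQCLASS", "Consequence class"),
        ("HGVSC", "cDNA change"), ("HGVSP", "Protein change"),
        ("PROVEAN", "PROVEAN verdict"), ("SIFT", "SIFT verdict"),
        ("POLYPHEN", "PolyPhen-2 verdict"),
    ]:
        lines.append(
            f'##INFO=<ID={key},Number=A,Type=String,Description="{desc}">')
    for src, (ac_key, an_key) in VCF_FREQUENCY_KEYS.items():
        lines.append(f'##INFO=<ID={ac_key},Number=A,Type=Integer,'
                     f'Description="Allele count {src}">')
        lines.append(f'##INFO=<ID={an_key},Number=1,Type=Integer,'
                     f'Description="Allele number {src}">')
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        info = [
            f"GENE={v.gene}",
            f"CSQCLASS={v.consequence.value}",
            f"HGVSC={v.hgvs_c}",
        ]
        if v.hgvs_p:
            info.append(f"HGVSP={v.hgvs_p}")
        p = v.predictions
        if p.provean is not ProveanCall.MISSING:
            info.append(f"PROVEAN={p.provean.value}")
        if p.sift is not SiftCall.MISSING:
            info.append(f"SIFT={p.sift.value}")
        if p.polyphen is not PolyphenCall.MISSING:
            info.append(f"POLYPHEN={p.polyphen.value}")
        for src, (ac_key, an_key) in VCF_FREQUENCY_KEYS.items():
            ac, an = v.frequencies.get(src, (0, 0))
            info.append(f"{ac_key}={ac}")
            info.append(f"{an_key}={an}")
        if v.depth is not None:
            info.append(f"DP={v.depth}")
        gts = []
        for sample in samples:
            z = family.genotype(sample, v.key)
            code = _GT_CODE[z]
            member = family.member(sample)
            if v.chrom == "chrX" and member is not None and \
                    member.sex is Sex.MALE and z is Zygosity.HOM_REF:
                code = "0"
            gts.append(code)
        qual = f"{v.quality:.1f}" if v.quality is not None else "."
        lines.append("\t".join([
            v.chrom, str(v.pos), ".", v.ref, v.alt, qual, "PASS",
            ";".join(info), "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
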