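"""Novelty calls, panel tiering, the uncertain-candidate rescue scan,
per-gene burden, and cohort-level yield summaries.

The cohort summary reproduces the tallies a diagnostic exome study
reports: how many families were solved overall and per declared
inheritance class, how many distinct mutations and genes were implicated,
and the novel/reported split against a literature catalog.  Mutations are
counted distinct by ``(gene, hgvs_c)`` so an allele shared by two families
counts once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .filter_cascade import (
    FilterPolicy,
    allele_frequency,
    max_reference_maf,
)
from .models import (
    CandidateUnit,
    Consequence,
    Family,
    GenePanel,
    InheritanceModel,
    KnownMutationCatalog,
    Novelty,
    Phase,
    ProveanCall,
    SiftCall,
    Tier,
    UnitModel,
    VariantKey,
    VariantRecord,
    Zygosity,
)


def classify_novelty(
    unit: CandidateUnit, catalog: KnownMutationCatalog,
) -> dict[VariantKey, Novelty]:
    """Per-variant novel/reported call by exact (gene, hgvs_c) lookup."""
    unit.novelty = {
        key: Novelty.REPORTED if key in catalog else Novelty.NOVEL
        for key in unit.variants
    }
    return unit.novelty


def assign_tier(
    unit: CandidateUnit,
    known_panel: GenePanel,
    other_panel: GenePanel | None = None,
) -> Tier:
    """Known-RP panel membership wins over the other-retinopathy panel;
    genes in neither panel leave the unit contributing to 'unsolved'."""
    if unit.gene in known_panel:
        unit.tier = Tier.KNOWN_RP_GENE
    elif other_panel is not None and unit.gene in other_panel:
        unit.tier = Tier.OTHER_RETINOPATHY_GENE
    else:
        unit.tier = Tier.UNSOLVED
    return unit.tier


def rescue_scan(
    families: list[Family],
    variants_by_family: dict[str, list[VariantRecord]],
    policy: FilterPolicy,
    solved_family_ids: set[str] | None = None,
    in_house_source: str = "in_house",
    require_both_predictors: bool = True,
) -> list[CandidateUnit]:
    """Second-pass scan for uncertain candidates among unsolved sporadic
    probands.

    Heterozygous missense variants are kept when (i) the in-house control
    MAF is below the recessive threshold, (ii) the variant is called
    deleterious by PROVEAN and damaging by SIFT (both, by default), and
    (iii) the maximum MAF across the *external* reference sources (the
    in-house source has its own gate in step i) does not exceed
    ``policy.maf_rescue`` (default 0.001).  Surviving variants are emitted
    as single-variant dominant-hypothesis units tiered uncertain_candidate.
    """
    solved_family_ids = solved_family_ids or set()
    units: list[CandidateUnit] = []
    for family in families:
        if family.declared_model is not InheritanceModel.SPORADIC:
            continue
        if family.family_id in solved_family_ids:
            continue
        proband = family.probands[0]
        for variant in variants_by_family.get(family.family_id, []):
            if family.genotype(proband.sample_id, variant.key) is not \
                    Zygosity.HET:
                continue
            if variant.consequence is not Consequence.NONSYNONYMOUS:
                continue
            ac, an = variant.frequencies.get(in_house_source, (0, 0))
            if allele_frequency(ac, an) >= policy.maf_recessive:
                continue
            p = variant.predictions
            provean_hit = p.provean is ProveanCall.DELETERIOUS
            sift_hit = p.sift is SiftCall.DAMAGING
            if require_both_predictors:
                if not (provean_hit and sift_hit):
                    continue
            elif not (provean_hit or sift_hit):
                continue
            external = [
                s for s in (policy.frequency_sources
                            or variant.frequencies)
                if s != in_house_source
            ]
            maf, _ = max_reference_maf(variant, external)
            if maf > policy.maf_rescue:
                continue
            unit = CandidateUnit(
                family_id=family.family_id, gene=variant.key[0],
                model=UnitModel.DOMINANT, variants=(variant.key,),
                phase=Phase.NOT_APPLICABLE, tier=Tier.UNCERTAIN_CANDIDATE,
            )
            units.append(unit)
    return units


def gene_burden(
    cohort_variants: list[VariantRecord],
    panel: GenePanel,
    n_samples: int,
    conserved_cutoff: float = 0.15,
) -> dict[str, tuple[float, bool]]:
    """Distinct nonsynonymous variants per panel gene per 100 samples.

    Genes at or below ``conserved_cutoff`` per 100 samples are flagged
    conserved (they tolerate very little missense variation in either
    patients or controls).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    distinct: dict[str, set[VariantKey]] = {g: set() for g in panel.entries}
    for v in cohort_variants:
        if v.gene in distinct and \
                v.consequence is Consequence.NONSYNONYMOUS:
            distinct[v.gene].add(v.key)
    return {
        gene: (
            len(keys) * 100.0 / n_samples,
            len(keys) * 100.0 / n_samples <= conserved_cutoff,
        )
        for gene, keys in distinct.items()
    }


@dataclass
class CohortSummary:
    """Printed-tally view of a prioritization run."""

    n_families_total: int = 0
    n_families_by_model: dict[str, int] = field(default_factory=dict)
    n_solved: int = 0
    n_solved_by_model: dict[str, int] = field(default_factory=dict)
    n_families_with_units: int = 0
    distinct_mutations: int = 0
    distinct_genes: int = 0
    n_novel: int = 0
    n_reported: int = 0
    per_gene: dict[str, tuple[int, float]] = field(default_factory=dict)
    per_tier: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_families_total": self.n_families_total,
            "n_families_by_model": self.n_families_by_model,
            "n_solved": self.n_solved,
            "n_solved_by_model": self.n_solved_by_model,
            "n_families_with_units": self.n_families_with_units,
            "distinct_mutations": self.distinct_mutations,
            "distinct_genes": self.distinct_genes,
            "n_novel": self.n_novel,
            "n_reported": self.n_reported,
            "per_gene": {
                g: {"n_families": n, "proportion": p}
                for g, (n, p) in self.per_gene.items()
            },
            "per_tier": self.per_tier,
            "solved_percent": round(
                100.0 * self.n_solved / self.n_families_total
            ) if self.n_families_total else 0,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize_cohort(
    families: list[Family],
    units: list[CandidateUnit],
    cohort_size: int | None = None,
) -> CohortSummary:
    """Aggregate surviving units into the cohort's printed tallies.

    ``solved`` counts families with at least one known-RP-panel unit;
    uncertain and other-retinopathy units never increment it.  Distinct
    mutations, genes and the novel/reported split are computed over all
    supplied units keyed by (gene, hgvs_c).  Per-gene proportions are over
    ``cohort_size`` (defaulting to the number of supplied families), with
    each family counted once per gene it has a unit in.
    """
    summary = CohortSummary()
    summary.n_families_total = cohort_size if cohort_size is not None \
        else len(families)
    for fam in families:
        m = fam.declared_model.value
        summary.n_families_by_model[m] = \
            summary.n_families_by_model.get(m, 0) + 1

    model_by_family = {f.family_id: f.declared_model.value for f in families}
    mutations: set[VariantKey] = set()
    novelty: dict[VariantKey, Novelty] = {}
    genes: set[str] = set()
    solved_families: set[str] = set()
    families_with_units: set[str] = set()
    gene_families: dict[str, set[str]] = {}
    for unit in units:
        families_with_units.add(unit.family_id)
        genes.add(unit.gene)
        gene_families.setdefault(unit.gene, set()).add(unit.family_id)
        for key in unit.variants:
            mutations.add(key)
            if key in unit.novelty:
                novelty[key] = unit.novelty[key]
        if unit.tier is Tier.KNOWN_RP_GENE:
            solved_families.add(unit.family_id)
        tier_name = unit.tier.value if unit.tier else "untiered"
        summary.per_tier[tier_name] = summary.per_tier.get(tier_name, 0) + 1

    summary.distinct_mutations = len(mutations)
    summary.distinct_genes = len(genes)
    summary.n_novel = sum(
        1 for k in mutations if novelty.get(k, Novelty.NOVEL) is Novelty.NOVEL
    )
    summary.n_reported = len(mutations) - summary.n_novel
    summary.n_solved = len(solved_families)
    summary.n_families_with_units = len(families_with_units)
    for fid in solved_families:
        m = model_by_family.get(fid, "unknown")
        summary.n_solved_by_model[m] = summary.n_solved_by_model.get(m, 0) + 1
    denom = summary.n_families_total or 1
    summary.per_gene = {
        gene: (len(fams), len(fams) / denom)
        for gene, fams in sorted(gene_families.items())
    }
    return summary


def units_to_rows(units: list[CandidateUnit]) -> list[dict]:
    rows = []
    for u in units:
        rows.append({
            "family": u.family_id,
            "gene": u.gene,
            "model": u.model.value,
            "variants": ";".join(k[1] for k in u.variants),
            "phase": u.phase.value,
            "de_novo": u.de_novo.value,
            "segregation": u.segregation.value,
            "novelty": ";".join(
                u.novelty.get(k, Novelty.NOVEL).value for k in u.variants
            ),
            "tier": u.tier.value if u.tier else "",
            "low_confidence": u.low_confidence,
        })
    return rows


def write_units_tsv(units: list[CandidateUnit], path: str | Path) -> None:
    rows = units_to_rows(units)
    cols = ["family", "gene", "model", "variants", "phase", "de_novo",
            "segregation", "novelty", "tier", "low_confidence"]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_units_tsv(path: str | Path) -> list[CandidateUnit]:
    """Re-load a units TSV written by :func:`write_units_tsv`."""
    from .models import DeNovoStatus, Segregation

    lines = Path(path).read_text().splitlines()
    units: list[CandidateUnit] = []
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        variants = tuple(
            (row["gene"], h) for h in row["variants"].split(";")
        )
        novelty_tokens = row["novelty"].split(";")
        unit = CandidateUnit(
            family_id=row["family"], gene=row["gene"],
            model=UnitModel(row["model"]), variants=variants,
            phase=Phase(row["phase"]),
            de_novo=DeNovoStatus(row["de_novo"]),
            segregation=Segregation(row["segregation"]),
            novelty={
                k: Novelty(tok) for k, tok in zip(variants, novelty_tokens)
            },
            tier=Tier(row["tier"]) if row["tier"] else None,
            low_confidence=row["low_confidence"] == "True",
        )
        units.append(unit)
    return units


def plot_gene_proportions(summary: CohortSummary, path: str | Path) -> None:
    """Bar chart of per-gene family proportions (diagnostic-yield figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(summary.per_gene)
    props = [100.0 * summary.per_gene[g][1] for g in genes]
    order = sorted(range(len(genes)), key=lambda i: -props[i])
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(genes)), 4))
    ax.bar([genes[i] for i in order], [props[i] for i in order],
           color="#4878a8")
    ax.set_ylabel("% of families")
    ax.set_xlabel("gene")
    ax.tick_params(axis="x", rotation=90, labelsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
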