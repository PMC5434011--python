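"""End-to-end prioritization: cascade -> inheritance engine -> reporting.

This is the composition layer every entry point (CLI, analysis drivers,
tests) calls; each stage lives in its own module and is independently
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .filter_cascade import FilterPolicy, FilterTrace, apply_cascade
from .inheritance_engine import build_units, flag_digenic
from .io_formats import (
    TableRow,
    families_from_table,
    variants_by_family,
)
from .models import (
    CandidateUnit,
    Family,
    GenePanel,
    KnownMutationCatalog,
    VariantRecord,
)
from .reporting import (
    CohortSummary,
    assign_tier,
    classify_novelty,
    summarize_cohort,
)


@dataclass
class PrioritizationResult:
    units: list[CandidateUnit]
    summary: CohortSummary
    traces: dict[str, FilterTrace] = field(default_factory=dict)
    digenic_pairs: list[tuple[CandidateUnit, CandidateUnit]] = field(
        default_factory=list
    )


def prioritize_cohort(
    families: list[Family],
    variants: dict[str, list[VariantRecord]],
    panel: GenePanel,
    catalog: KnownMutationCatalog,
    policy: FilterPolicy | None = None,
    other_panel: GenePanel | None = None,
    cohort_size: int | None = None,
    known_panel: GenePanel | None = None,
) -> PrioritizationResult:
    """Run the full prioritization over a cohort of families.

    ``variants`` maps family id to that family's annotated variants; the
    cascade runs per family under its declared inheritance model, the
    inheritance engine forms and screens candidate units against the
    pedigree, and reporting attaches novelty/tier and tallies the cohort.

    ``panel`` drives unit formation.  Tiering compares unit genes against
    ``known_panel`` (defaulting to ``panel``) and then ``other_panel``:
    a second-tier run forms units in the other-retinopathy panel but
    passes the known-RP panel here so its units tier correctly.
    """
    policy = policy or FilterPolicy()
    all_units: list[CandidateUnit] = []
    traces: dict[str, FilterTrace] = {}
    digenic: list[tuple[CandidateUnit, CandidateUnit]] = []
    for family in sorted(families, key=lambda f: f.family_id):
        family.validate()
        fam_variants = variants.get(family.family_id, [])
        retained, trace = apply_cascade(
            fam_variants, family.declared_model, policy,
        )
        traces[family.family_id] = trace
        units = build_units(family, retained, panel, policy)
        for unit in units:
            classify_novelty(unit, catalog)
            assign_tier(unit, known_panel or panel, other_panel)
        digenic.extend(flag_digenic(family, units))
        all_units.extend(units)
    summary = summarize_cohort(families, all_units, cohort_size=cohort_size)
    return PrioritizationResult(
        units=all_units, summary=summary, traces=traces,
        digenic_pairs=digenic,
    )


def prioritize_table(
    rows: list[TableRow],
    panel: GenePanel,
    catalog: KnownMutationCatalog,
    policy: FilterPolicy | None = None,
    other_panel: GenePanel | None = None,
    cohort_size: int | None = None,
    known_panel: GenePanel | None = None,
) -> PrioritizationResult:
    """Convenience wrapper: run the pipeline on annotated-table rows."""
    families = families_from_table(rows)
    return prioritize_cohort(
        families, variants_by_family(rows), panel, catalog, policy,
        other_panel=other_panel, cohort_size=cohort_size,
        known_panel=known_panel,
    )
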