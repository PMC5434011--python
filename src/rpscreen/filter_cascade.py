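"""Variant-level QC and the four-step rarity/consequence/predictor cascade.

The cascade retains a variant for a family when it:

1. passes call QC — phred quality strictly above Q30, read depth >= 5x,
   and (optionally) lies outside an excluded-region interval set such as
   the MHC-homologous sequence;
2. is sufficiently rare in every consulted reference population — absent
   from all references under a dominant model ("any frequency" excludes),
   MAF <= 0.005 under recessive or X-linked models;
3. is coding or splice-altering (noncoding and synonymous variants are
   excluded unless they alter a splice site);
4. is not called benign by all three missense predictors simultaneously.

Step 4 is applied here only to missense variants that will stand alone as
single-variant candidates; for two-variant (compound-het) units the
predictor exclusion is a pair-level rule and is delegated to the
inheritance engine, which keeps a pair as long as at least one allele is
not triple-benign.  Steps short-circuit in the fixed order QC -> frequency
-> consequence -> predictor and the trace records the first failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import (
    Consequence,
    InheritanceModel,
    PolyphenCall,
    PredictionTriple,
    ProveanCall,
    SiftCall,
    SPLICE_ALTERING,
    VariantRecord,
)

log = logging.getLogger(__name__)


@dataclass
class FilterPolicy:
    """All thresholds of the cascade.

    ``maf_dominant`` = 0 encodes the "any frequency excludes" dominant
    rule; ``maf_rescue`` is the stricter ceiling used by the uncertain-
    candidate rescue scan.  ``frequency_sources`` limits which reference
    sources are consulted; ``None`` consults every source annotated on the
    variant.
    """

    min_quality: float = 30.0
    min_depth: int = 5
    maf_recessive: float = 0.005
    maf_dominant: float = 0.0
    maf_rescue: float = 0.001
    frequency_sources: list[str] | None = None
    excluded_regions: "IntervalSet | None" = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_dominant <= self.maf_rescue
                <= self.maf_recessive <= 1.0):
            raise ValueError(
                "need 0 <= maf_dominant <= maf_rescue <= maf_recessive <= 1"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterPolicy":
        """Load thresholds from a YAML key-value file (keys mirror fields)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bed = raw.pop("excluded_regions_bed", None)
        policy = cls(**raw)
        if bed:
            policy.excluded_regions = IntervalSet.from_bed(bed)
        return policy


class IntervalSet:
    """Genomic interval set with BED semantics (0-based half-open)."""

    def __init__(self) -> None:
        self._trees: dict[str, "object"] = {}

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        from intervaltree import IntervalTree

        out = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            tree = out._trees.setdefault(chrom, IntervalTree())
            tree.addi(int(start), int(end))
        return out

    def contains(self, chrom: str, pos_1based: int) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos_1based - 1, pos_1based))


@dataclass
class FilterTrace:
    """Ordered audit of (step, pass/fail, reason) per variant key."""

    steps: dict[tuple[str, str], list[tuple[str, bool, str]]] = field(
        default_factory=dict
    )

    def record(self, key: tuple[str, str], step: str, ok: bool,
               reason: str) -> None:
        self.steps.setdefault(key, []).append((step, ok, reason))

    def to_rows(self) -> list[dict]:
        return [
            {"gene": k[0], "hgvs_c": k[1], "step": step,
             "passed": ok, "reason": reason}
            for k, entries in self.steps.items()
            for step, ok, reason in entries
        ]


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """AC/AN, with the no-observation convention 0/0 -> 0.0.

    A source with zero observed alleles says nothing about rarity either
    way; treating it as frequency 0 keeps absence-from-reference distinct
    from observed-common.
    """
    if allele_number < 0:
        raise ValueError("allele_number must be >= 0")
    if allele_count > allele_number:
        raise ValueError(
            f"allele_count {allele_count} > allele_number {allele_number}"
        )
    if allele_number == 0:
        return 0.0
    return allele_count / allele_number


def max_reference_maf(
    variant: VariantRecord, sources: list[str] | None = None,
) -> tuple[float, str | None]:
    """Maximum allele frequency over the consulted sources.

    Returns the attaining source name; a variant absent from a source
    contributes 0.  An empty frequency map yields ``(0.0, None)``.
    """
    consulted = sources if sources is not None else list(variant.frequencies)
    best, best_source = 0.0, None
    for source in consulted:
        ac, an = variant.frequencies.get(source, (0, 0))
        freq = allele_frequency(ac, an)
        if freq > best:
            best, best_source = freq, source
    return best, best_source


def qc_pass(variant: VariantRecord, policy: FilterPolicy) -> bool:
    """Call-quality gate: quality strictly > Q30, depth >= 5x, no region hit.

    Variants lacking quality/depth annotation (table-fixture mode) pass
    with a debug log entry — published tables ship only post-QC calls.
    """
    if variant.quality is not None and not variant.quality > policy.min_quality:
        return False
    if variant.depth is not None and variant.depth < policy.min_depth:
        return False
    if variant.quality is None and variant.depth is None:
        log.debug("no QC annotation on %s; treated as passing", variant.key)
    if policy.excluded_regions is not None and variant.chrom:
        if policy.excluded_regions.contains(variant.chrom, variant.pos):
            return False
    return True


def frequency_pass(
    variant: VariantRecord, model: InheritanceModel, policy: FilterPolicy,
) -> bool:
    """Model-dependent rarity gate over the consulted reference sources.

    Dominant: any nonzero reference frequency excludes (threshold 0).
    Recessive and X-linked: maximum reference MAF must not exceed 0.005.
    Sporadic families are screened at the recessive threshold; the
    inheritance engine re-imposes the dominant rule when it forms a
    dominant unit for a sporadic family.
    """
    maf, _ = max_reference_maf(variant, policy.frequency_sources)
    if model is InheritanceModel.DOMINANT:
        return maf <= policy.maf_dominant
    if model in (InheritanceModel.RECESSIVE, InheritanceModel.XLINKED,
                 InheritanceModel.SPORADIC):
        return maf <= policy.maf_recessive
    raise ValueError(f"unknown inheritance model {model!r}")


def consequence_pass(variant: VariantRecord) -> bool:
    """Exclude noncoding and synonymous variants unless splice-altering."""
    if variant.consequence in (Consequence.NONCODING, Consequence.SYNONYMOUS):
        return variant.consequence in SPLICE_ALTERING
    return True


def triple_benign(predictions: PredictionTriple) -> bool:
    """True iff all three predictors simultaneously call the variant benign.

    Any missing verdict returns False: simultaneous benignity cannot be
    asserted, so truncating/splicing variants (all-missing) are never
    predictor-excluded.
    """
    return (
        predictions.provean is ProveanCall.NEUTRAL
        and predictions.sift is SiftCall.TOLERATED
        and predictions.polyphen is PolyphenCall.BENIGN
    )


def apply_cascade(
    variants: list[VariantRecord],
    model: InheritanceModel,
    policy: FilterPolicy,
    defer_predictor_exclusion: bool = True,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run the four-step cascade over a family's variants.

    With ``defer_predictor_exclusion`` (the default), step 4 is left to the
    inheritance engine's pair-aware rule; single-variant units are still
    excluded there when triple-benign.  Passing ``False`` applies the
    strict per-variant step-4 reading, used by the brute-force oracle tests.
    """
    retained: list[VariantRecord] = []
    trace = FilterTrace()
    for variant in variants:
        key = variant.key
        if not qc_pass(variant, policy):
            trace.record(key, "qc", False, "quality/depth/region gate")
            continue
        trace.record(key, "qc", True, "")
        if not frequency_pass(variant, model, policy):
            maf, source = max_reference_maf(variant, policy.frequency_sources)
            trace.record(key, "frequency", False,
                         f"MAF {maf:.3g} in {source} exceeds {model.value} "
                         f"threshold")
            continue
        trace.record(key, "frequency", True, "")
        if not consequence_pass(variant):
            trace.record(key, "consequence", False,
                         f"{variant.consequence.value} without splice effect")
            continue
        trace.record(key, "consequence", True, "")
        if not defer_predictor_exclusion and triple_benign(variant.predictions):
            trace.record(key, "predictor", False,
                         "Neutral/Tolerated/Benign by all three predictors")
            continue
        trace.record(key, "predictor", True,
                     "" if not defer_predictor_exclusion
                     else "deferred to unit-level rule")
        retained.append(variant)
    return retained, trace
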