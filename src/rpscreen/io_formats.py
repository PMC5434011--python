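"""Readers and writers for the external formats the pipeline consumes.

Formats
-------
* PED pedigrees (standard 6-column dialect, whitespace-delimited).
* The annotated-variant table dialect: a tab-separated file with one row
  per (family, allele) carrying the gene, declared family inheritance
  model, the cDNA/protein change, the genotype configuration observed in
  the proband, the consequence class, the three predictor verdicts, a
  reported/novel flag and optional per-source allele counts.  The bundled
  study tables ship in this dialect.
* Annotated VCF 4.x with per-sample genotypes (via cyvcf2), with the
  annotation INFO keys supplied by the caller.
* Two-column gene panels (gene, comma-separated modes) and known-mutation
  catalogs (gene, hgvs_c, optional literature tag).

Predictor tokens are normalized case-insensitively; the mapping for
irregular tokens seen in published tables ("possibly neutral",
"possibly deleterious") lives in :data:`POLYPHEN_TOKEN_MAP` and can be
extended by callers.  HGVS strings are opaque normalized tokens: whitespace
is stripped and the ``A > G`` spacing collapsed; no HGVS grammar is parsed.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .models import (
    Affection,
    Consequence,
    Family,
    GenePanel,
    Individual,
    InheritanceModel,
    KnownMutationCatalog,
    Mode,
    PolyphenCall,
    PredictionTriple,
    ProveanCall,
    Sex,
    SiftCall,
    VariantKey,
    VariantRecord,
    Zygosity,
)

log = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "gene", "model", "family", "hgvs_c", "hgvs_p", "change",
    "consequence", "provean", "sift", "polyphen", "reported", "frequencies",
]

#: Genotype-configuration keywords accepted in the ``change`` column.
CHANGE_TOKENS = {
    "heterozygous": Zygosity.HET,
    "homozygous": Zygosity.HOM_ALT,
    "compound_heterozygous": Zygosity.HET,
    "compound heterozygous": Zygosity.HET,
    "hemizygote": Zygosity.HEMIZYGOUS,
    "hemizygous": Zygosity.HEMIZYGOUS,
}

MODEL_TOKENS = {
    "dominant": InheritanceModel.DOMINANT,
    "recessive": InheritanceModel.RECESSIVE,
    "sporadic": InheritanceModel.SPORADIC,
    "x-linked": InheritanceModel.XLINKED,
    "xlinked": InheritanceModel.XLINKED,
    "xl": InheritanceModel.XLINKED,
}

CONSEQUENCE_TOKEN_MAP = {
    "splice-acceptor": Consequence.SPLICE_ACCEPTOR_REGION,
    "splice acceptor": Consequence.SPLICE_ACCEPTOR_REGION,
}

# Case-insensitive prefix rules for PolyPhen-2; irregular tokens from
# published tables map onto the closed vocabulary.  Editable resource.
POLYPHEN_TOKEN_MAP = {
    "probably damaging": PolyphenCall.PROBABLY_DAMAGING,
    "probably_damaging": PolyphenCall.PROBABLY_DAMAGING,
    "possibly damaging": PolyphenCall.POSSIBLY_DAMAGING,
    "possibly_damaging": PolyphenCall.POSSIBLY_DAMAGING,
    "possibly deleterious": PolyphenCall.POSSIBLY_DAMAGING,
    "possibly neutral": PolyphenCall.BENIGN,
    "benign": PolyphenCall.BENIGN,
}

MISSING_TOKENS = {"", "na", "nan", ".", "-", "none", "missing"}


class ParseError(ValueError):
    """Raised for malformed rows; carries file and row context."""


def normalize_hgvs(token: str) -> str:
    """Canonicalize an HGVS string as an opaque token.

    Strips whitespace (including the ``A > G`` spacing common in published
    tables) and trailing unmatched parentheses; performs no grammatical
    parsing.
    """
    t = re.sub(r"\s+", "", token.strip())
    if t.count(")") > t.count("("):
        t = t.rstrip(")")
    return t


def normalize_provean(token: str) -> ProveanCall:
    t = token.strip().lower()
    if t in MISSING_TOKENS:
        return ProveanCall.MISSING
    if t.startswith("deleterious"):
        return ProveanCall.DELETERIOUS
    if t.startswith("neutral"):
        return ProveanCall.NEUTRAL
    raise ParseError(f"unknown PROVEAN token {token!r}")


def normalize_sift(token: str) -> SiftCall:
    t = token.strip().lower()
    if t in MISSING_TOKENS:
        return SiftCall.MISSING
    if t.startswith("damaging"):
        return SiftCall.DAMAGING
    if t.startswith("tolerated"):
        return SiftCall.TOLERATED
    raise ParseError(f"unknown SIFT token {token!r}")


def normalize_polyphen(token: str) -> PolyphenCall:
    t = token.strip().lower()
    if t in MISSING_TOKENS:
        return PolyphenCall.MISSING
    if t in POLYPHEN_TOKEN_MAP:
        return POLYPHEN_TOKEN_MAP[t]
    raise ParseError(f"unknown PolyPhen-2 token {token!r}")


def normalize_consequence(token: str) -> Consequence:
    t = token.strip().lower().replace(" ", "_")
    if t in CONSEQUENCE_TOKEN_MAP:
        return CONSEQUENCE_TOKEN_MAP[t]
    t2 = token.strip().lower()
    if t2 in CONSEQUENCE_TOKEN_MAP:
        return CONSEQUENCE_TOKEN_MAP[t2]
    try:
        return Consequence(t)
    except ValueError:
        raise ParseError(f"unknown consequence token {token!r}") from None


def _parse_frequencies(token: str) -> dict[str, tuple[int, int]]:
    """Parse ``source:AC/AN;source:AC/AN`` into a frequency map."""
    token = token.strip()
    if not token or token.lower() in MISSING_TOKENS:
        return {}
    out: dict[str, tuple[int, int]] = {}
    for part in token.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            source, counts = part.split(":")
            ac_s, an_s = counts.split("/")
            out[source.strip()] = (int(ac_s), int(an_s))
        except ValueError:
            raise ParseError(f"malformed frequency field {part!r}") from None
    return out


def _format_frequencies(freqs: dict[str, tuple[int, int]]) -> str:
    return ";".join(f"{s}:{ac}/{an}" for s, (ac, an) in freqs.items())


# ---------------------------------------------------------------------------
# PED pedigrees

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFF = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_ped(path: str | Path) -> list[Individual]:
    """Read a 6-column PED file into :class:`Individual` records.

    Phenotype code 2 maps to affected, 1 to unaffected, 0/-9 to unknown.
    Parent references are validated: a parent id that never appears as an
    individual in the file is a structural error.
    """
    individuals: list[Individual] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 PED columns")
        fam, iid, father, mother, sex, pheno = fields[:6]
        if iid in seen:
            raise ParseError(f"{path}:{lineno}: duplicated sample id {iid!r}")
        seen.add(iid)
        individuals.append(Individual(
            sample_id=iid,
            family_id=fam,
            father_id="" if father == "0" else father,
            mother_id="" if mother == "0" else mother,
            sex=_PED_SEX.get(sex, Sex.UNKNOWN),
            affected=_PED_AFF.get(pheno, Affection.UNKNOWN),
        ))
    ids = {i.sample_id for i in individuals}
    for ind in individuals:
        for parent, label in ((ind.father_id, "father"),
                              (ind.mother_id, "mother")):
            if parent and parent not in ids:
                raise ParseError(
                    f"{path}: {label} {parent!r} of {ind.sample_id!r} "
                    f"is not in the pedigree"
                )
    return individuals


def write_ped(individuals: Iterable[Individual], path: str | Path) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
                Affection.UNKNOWN: "0"}
    lines = []
    for i in individuals:
        lines.append("\t".join([
            i.family_id, i.sample_id,
            i.father_id or "0", i.mother_id or "0",
            sex_code[i.sex], aff_code[i.affected],
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotated variant tables

#: One parsed table row: the family label, its declared model, the variant
#: and the genotype-configuration keyword observed in the proband.
TableRow = tuple[str, InheritanceModel, VariantRecord, str]


def read_variant_table(path: str | Path) -> list[TableRow]:
    """Read the tab-separated annotated-variant dialect.

    Returns one entry per row as ``(family_id, declared_model,
    VariantRecord, change_keyword)`` with ``change_keyword`` normalized to
    one of ``heterozygous | homozygous | compound_heterozygous |
    hemizygote``.
    """
    text = Path(path).read_text()
    rows: list[TableRow] = []
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        return rows
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:len(TABLE_COLUMNS)]] != \
            TABLE_COLUMNS[:len(header)]:
        raise ParseError(
            f"{path}: unexpected header {header!r}; expected {TABLE_COLUMNS}"
        )
    idx = {name: i for i, name in enumerate(header)}
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.rstrip("\n").split("\t")

        def get(col: str) -> str:
            i = idx.get(col)
            return fields[i].strip() if i is not None and i < len(fields) else ""

        change = get("change").lower().replace("_", " ").strip()
        change_norm = change.replace(" ", "_")
        if change_norm not in {"heterozygous", "homozygous",
                               "compound_heterozygous", "hemizygote",
                               "hemizygous"}:
            raise ParseError(
                f"{path}:{lineno}: unknown change token {get('change')!r}"
            )
        if change_norm == "hemizygous":
            change_norm = "hemizygote"
        model_token = get("model").lower()
        if model_token not in MODEL_TOKENS:
            raise ParseError(
                f"{path}:{lineno}: unknown model token {get('model')!r}"
            )
        try:
            record = VariantRecord(
                gene=get("gene"),
                hgvs_c=normalize_hgvs(get("hgvs_c")),
                hgvs_p=normalize_hgvs(get("hgvs_p")),
                consequence=normalize_consequence(get("consequence")),
                predictions=PredictionTriple(
                    provean=normalize_provean(get("provean")),
                    sift=normalize_sift(get("sift")),
                    polyphen=normalize_polyphen(get("polyphen")),
                ),
                frequencies=_parse_frequencies(get("frequencies")),
            )
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if not record.gene or not record.hgvs_c:
            raise ParseError(f"{path}:{lineno}: gene and hgvs_c are required")
        record.__dict__["reported_tag"] = get("reported")
        rows.append((get("family"), MODEL_TOKENS[model_token], record,
                     change_norm))
    return rows


def reported_tag(record: VariantRecord) -> str:
    """Literature tag carried by a table row ('' or 'Novel' means novel)."""
    tag = record.__dict__.get("reported_tag", "")
    return "" if tag.strip().lower() in {"", "novel"} else tag.strip()


def write_variant_table(rows: Sequence[TableRow], path: str | Path) -> None:
    """Write rows in the same dialect ``read_variant_table`` reads."""
    model_out = {
        InheritanceModel.DOMINANT: "dominant",
        InheritanceModel.RECESSIVE: "recessive",
        InheritanceModel.SPORADIC: "sporadic",
        InheritanceModel.XLINKED: "X-linked",
    }
    lines = ["\t".join(TABLE_COLUMNS)]
    for family_id, model, rec, change in rows:
        lines.append("\t".join([
            rec.gene, model_out[model], family_id, rec.hgvs_c, rec.hgvs_p,
            change.replace("_", " ") if change == "compound_heterozygous"
            else change,
            rec.consequence.value,
            rec.predictions.provean.value
            if rec.predictions.provean is not ProveanCall.MISSING else "NA",
            rec.predictions.sift.value
            if rec.predictions.sift is not SiftCall.MISSING else "NA",
            rec.predictions.polyphen.value.replace("_", " ")
            if rec.predictions.polyphen is not PolyphenCall.MISSING else "NA",
            rec.__dict__.get("reported_tag", "") or "Novel",
            _format_frequencies(rec.frequencies),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def families_from_table(rows: Sequence[TableRow]) -> list[Family]:
    """Build single-proband :class:`Family` objects from table rows.

    The table dialect records only the proband's genotype configuration, so
    each family gets one affected, sequenced proband whose zygosity at each
    listed variant follows the ``change`` keyword.  Hemizygote rows imply a
    male proband.
    """
    by_family: dict[str, list[TableRow]] = {}
    order: list[str] = []
    for row in rows:
        fid = row[0]
        if fid not in by_family:
            by_family[fid] = []
            order.append(fid)
        by_family[fid].append(row)

    families: list[Family] = []
    for fid in order:
        frows = by_family[fid]
        model = frows[0][1]
        sex = Sex.MALE if any(r[3] == "hemizygote" for r in frows) \
            else Sex.UNKNOWN
        proband_id = f"{fid}_proband"
        proband = Individual(
            sample_id=proband_id, family_id=fid, sex=sex,
            affected=Affection.AFFECTED, sequenced=True,
        )
        genotypes: dict[tuple[str, VariantKey], Zygosity] = {}
        for _, _, rec, change in frows:
            genotypes[(proband_id, rec.key)] = CHANGE_TOKENS[change]
        families.append(Family(
            family_id=fid, members=[proband], declared_model=model,
            genotypes=genotypes,
        ))
    return families


def variants_by_family(rows: Sequence[TableRow]) -> dict[str, list[VariantRecord]]:
    out: dict[str, list[VariantRecord]] = {}
    for fid, _, rec, _ in rows:
        out.setdefault(fid, []).append(rec)
    return out


# ---------------------------------------------------------------------------
# Annotated VCF

DEFAULT_VCF_KEYS = {
    "gene": "GENE",
    "consequence": "CSQCLASS",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "provean": "PROVEAN",
    "sift": "SIFT",
    "polyphen": "POLYPHEN",
}

_X_CHROMS = {"X", "chrX", "chrS_X"}


def read_annotated_vcf(
    path: str | Path,
    annotation_key_map: dict[str, str] | None = None,
    frequency_keys: dict[str, tuple[str, str]] | None = None,
    pedigree: Sequence[Individual] | None = None,
) -> list[tuple[str, VariantRecord, dict[str, Zygosity]]]:
    """Read an annotated VCF into variant records plus per-sample zygosity.

    Multi-allelic records are split into one :class:`VariantRecord` per ALT
    allele (indels left-trimmed).  ``annotation_key_map`` maps the concept
    names of :data:`DEFAULT_VCF_KEYS` to the INFO keys the file actually
    uses; ``frequency_keys`` maps a source name to its (AC, AN) INFO keys.
    Haploid calls on X in male samples become hemizygous; male X het calls
    are coerced to missing with a warning (not genuinely het outside the
    pseudoautosomal regions, which are not modeled).
    """
    from cyvcf2 import VCF  # deferred: import cost, and only VCF mode needs it

    keys = dict(DEFAULT_VCF_KEYS)
    if annotation_key_map:
        keys.update(annotation_key_map)
    frequency_keys = frequency_keys or {}
    sex_by_sample = {
        i.sample_id: i.sex for i in (pedigree or [])
    }

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[tuple[str, VariantRecord, dict[str, Zygosity]]] = []
    for rec in vcf:
        info = dict(rec.INFO)
        for concept in ("gene", "consequence", "hgvs_c"):
            if keys[concept] not in info:
                raise ParseError(
                    f"{path}: record {rec.CHROM}:{rec.POS} missing mandatory "
                    f"annotation key {keys[concept]!r}"
                )
        n_alt = len(rec.ALT)

        def split_field(value: str) -> list[str]:
            parts = str(value).split(",")
            return parts if len(parts) == n_alt else [parts[0]] * n_alt

        genes = split_field(info[keys["gene"]])
        csqs = split_field(info[keys["consequence"]])
        hgvs_cs = split_field(info[keys["hgvs_c"]])
        hgvs_ps = split_field(info.get(keys["hgvs_p"], ""))
        provs = split_field(info.get(keys["provean"], "NA"))
        sifts = split_field(info.get(keys["sift"], "NA"))
        polys = split_field(info.get(keys["polyphen"], "NA"))

        on_x = rec.CHROM in _X_CHROMS
        for ai, alt in enumerate(rec.ALT):
            ref, alt_norm, pos = _left_trim(rec.REF, alt, rec.POS)
            freqs: dict[str, tuple[int, int]] = {}
            for source, (ac_key, an_key) in frequency_keys.items():
                if ac_key in info and an_key in info:
                    ac = info[ac_key]
                    an = info[an_key]
                    ac_i = int(split_field(str(ac))[ai])
                    freqs[source] = (ac_i, int(an))
            variant = VariantRecord(
                gene=genes[ai],
                hgvs_c=normalize_hgvs(hgvs_cs[ai]),
                hgvs_p=normalize_hgvs(hgvs_ps[ai]) if hgvs_ps[ai] else "",
                chrom=rec.CHROM, pos=pos, ref=ref, alt=alt_norm,
                consequence=normalize_consequence(csqs[ai]),
                predictions=PredictionTriple(
                    provean=normalize_provean(provs[ai]),
                    sift=normalize_sift(sifts[ai]),
                    polyphen=normalize_polyphen(polys[ai]),
                ),
                frequencies=freqs,
                quality=rec.QUAL,
                depth=_record_depth(rec),
            )
            calls: dict[str, Zygosity] = {}
            for si, sample in enumerate(samples):
                gt = rec.genotypes[si]  # [allele, allele, phased] or [allele, phased]
                alleles = [a for a in gt[:-1] if a is not None]
                zyg = _zygosity_from_alleles(
                    alleles, ai + 1,
                    male=sex_by_sample.get(sample) is Sex.MALE, on_x=on_x,
                    context=f"{path}:{rec.CHROM}:{rec.POS}:{sample}",
                )
                calls[sample] = zyg
            out.append((rec.CHROM, variant, calls))
    return out


def _left_trim(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Minimal left normalization: trim shared suffix then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def _record_depth(rec) -> int | None:
    try:
        dp = rec.INFO.get("DP")
        return int(dp) if dp is not None else None
    except (TypeError, ValueError):
        return None


def _zygosity_from_alleles(
    alleles: list[int], alt_index: int, male: bool, on_x: bool, context: str,
) -> Zygosity:
    if not alleles or any(a < 0 for a in alleles):
        return Zygosity.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        if n_alt == 0:
            return Zygosity.HOM_REF
        return Zygosity.HEMIZYGOUS if (on_x and male) else Zygosity.HOM_ALT
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt == len(alleles):
        return Zygosity.HEMIZYGOUS if (on_x and male) else Zygosity.HOM_ALT
    if on_x and male:
        log.warning("male X het call coerced to missing at %s", context)
        return Zygosity.MISSING
    return Zygosity.HET


def read_model_map(path: str | Path) -> dict[str, InheritanceModel]:
    """Two-column (family_id, declared model) file."""
    out: dict[str, InheritanceModel] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or fields[1].lower() not in MODEL_TOKENS:
            raise ParseError(f"{path}:{lineno}: expected family<TAB>model")
        out[fields[0]] = MODEL_TOKENS[fields[1].lower()]
    return out


def write_model_map(models: dict[str, InheritanceModel],
                    path: str | Path) -> None:
    lines = [f"{fid}\t{m.value}" for fid, m in models.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_vcf_cohort(
    vcf_dir: str | Path,
    ped_path: str | Path,
    models: dict[str, InheritanceModel] | str | Path,
    annotation_key_map: dict[str, str] | None = None,
    frequency_keys: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[Family], dict[str, list[VariantRecord]]]:
    """Assemble a cohort from per-family annotated VCFs plus one PED.

    Each ``<family_id>.vcf`` in ``vcf_dir`` is read with
    :func:`read_annotated_vcf`; pedigree structure and affection come from
    the PED and the declared inheritance model per family from ``models``
    (a mapping or a two-column file).
    """
    if not isinstance(models, dict):
        models = read_model_map(models)
    individuals = read_ped(ped_path)
    by_family: dict[str, list[Individual]] = {}
    for ind in individuals:
        by_family.setdefault(ind.family_id, []).append(ind)

    families: list[Family] = []
    variants: dict[str, list[VariantRecord]] = {}
    for fid in sorted(by_family):
        vcf_path = Path(vcf_dir) / f"{fid}.vcf"
        if not vcf_path.exists():
            raise ParseError(f"no VCF for family {fid}: {vcf_path}")
        if fid not in models:
            raise ParseError(f"no declared model for family {fid}")
        members = by_family[fid]
        family = Family(family_id=fid, members=members,
                        declared_model=models[fid])
        records = read_annotated_vcf(
            vcf_path, annotation_key_map=annotation_key_map,
            frequency_keys=frequency_keys, pedigree=members)
        fam_variants: list[VariantRecord] = []
        for _, variant, calls in records:
            fam_variants.append(variant)
            for sample, zygosity in calls.items():
                family.genotypes[(sample, variant.key)] = zygosity
        families.append(family)
        variants[fid] = fam_variants
    return families, variants


# ---------------------------------------------------------------------------
# Panels and catalogs

def load_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Load a two-column (gene, comma-separated modes) panel file."""
    entries: dict[str, frozenset[Mode]] = {}
    p = Path(path)
    for lineno, line in enumerate(p.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"\t|\s{2,}| ", line, maxsplit=1)
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>modes'")
        gene, modes_s = fields[0].strip(), fields[1].strip()
        modes = frozenset(Mode(m.strip().lower())
                          for m in modes_s.split(",") if m.strip())
        if not modes:
            raise ParseError(f"{path}:{lineno}: gene {gene} has no modes")
        entries[gene] = modes
    return GenePanel(name=name or p.stem, entries=entries)


def load_catalog(path: str | Path) -> KnownMutationCatalog:
    """Load a known-mutation catalog: gene, hgvs_c, optional tag."""
    entries: dict[VariantKey, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected gene<TAB>hgvs_c")
        gene, hgvs = fields[0].strip(), normalize_hgvs(fields[1])
        tag = fields[2].strip() if len(fields) > 2 else ""
        entries[(gene, hgvs)] = tag
    return KnownMutationCatalog(entries=entries)


# ---------------------------------------------------------------------------
# Bundled fixtures (transcriptions of the study's published tables)

def fixture_path(filename: str) -> Path:
    return Path(str(resources.files("rpscreen.data").joinpath(filename)))


def load_known_rp_table() -> list[TableRow]:
    """The 58-row known-RP-gene mutation table."""
    return read_variant_table(fixture_path("known_rp_mutations.tsv"))


def load_other_retinopathy_table() -> list[TableRow]:
    """The 17-row other-retinopathy-gene mutation table."""
    return read_variant_table(fixture_path("other_retinopathy_mutations.tsv"))


def load_rescue_table() -> list[TableRow]:
    """The 3-row uncertain-candidate table with per-source allele counts."""
    return read_variant_table(fixture_path("rescue_candidates.tsv"))


def load_known_rp_panel() -> GenePanel:
    return load_panel(fixture_path("panel_known_rp.tsv"), name="known_rp")


def load_other_retinopathy_panel() -> GenePanel:
    return load_panel(fixture_path("panel_other_retinopathy.tsv"),
                      name="other_retinopathy")


def load_reported_catalog() -> KnownMutationCatalog:
    return load_catalog(fixture_path("reported_mutations.tsv"))
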