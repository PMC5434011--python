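# Methods

## Model and assumptions

The package treats rare-disease diagnosis in a small family as a
deterministic rule system, not a statistical model: a candidate causal
genotype ("unit") is a set of one or two alleles in one gene that is (a)
technically credible, (b) rare enough for a Mendelian disease, (c)
functionally plausible, and (d) consistent with the pedigree. Each clause
is a separate, auditable rule; the pipeline is the conjunction.

Assumptions worth making explicit:

* **Annotations are inputs.** Consequence classes, PROVEAN/SIFT/PolyPhen-2
  verdicts and per-source allele counts arrive on the variants; the
  package never computes them. Garbage annotations produce garbage units.
* **One proband drives unit formation.** Families may contain several
  affected members; the first affected, sequenced member anchors genotype
  configuration, and all other members contribute through segregation and
  phasing rules.
* **Variant identity is `(gene, hgvs_c)`.** The published tables this
  package bundles omit genomic coordinates, so cDNA-change strings are
  treated as opaque normalized tokens (whitespace stripped, `A > G`
  spacing collapsed, unmatched trailing parentheses dropped). No HGVS
  grammar is parsed: fixtures only require equality.
* **Male X heterozygotes do not exist.** Outside pseudoautosomal regions
  (not modeled), a male X call of 0/1 is a genotyping artifact and is
  coerced to missing with a warning.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| `min_quality` | 30 (phred) | call quality must be strictly greater |
| `min_depth` | 5 (reads) | minimum read depth |
| `maf_recessive` | 0.005 | reference-MAF ceiling, recessive/X-linked |
| `maf_dominant` | 0.0 | dominant ceiling — any reference observation excludes |
| `maf_rescue` | 0.001 | external-reference ceiling in the rescue scan |
| `conserved_cutoff` | 0.15 /100 samples | gene-burden level flagged conserved |

Design choices where the procedure was genuinely open:

* **"Any frequency" as threshold zero.** The dominant rule is formalized
  as `maf_dominant = 0`: a variant observed even once in any consulted
  reference is excluded under a dominant hypothesis. A membership-only
  resource (e.g. a common-SNP catalog) is modeled as a presence/absence
  source with AC/AN = (1,1) — membership, not a numeric MAF, is what gets
  filtered on.
* **X-linked threshold.** No separate ceiling is defined for X-linked
  genes; they use the recessive 0.005 because carrier females appear in
  population references at carrier, not disease, frequencies.
* **Pair-level predictor rule.** Applying the triple-benign exclusion per
  variant would delete one allele of a genuine compound het whose partner
  is clearly damaging (the bundled tables contain exactly this case), so
  single-variant units are excluded when their missense allele is
  triple-benign, and two-variant units only when *both* alleles are.
  Missing verdicts never exclude: truncating and splice variants carry no
  predictor calls by design.
* **Recessive explanation beats dominant, per gene.** In a family whose
  gene shows a homozygous or trans-compatible pair, single-het dominant
  hypotheses for that same gene are suppressed: two qualifying hits in a
  recessive-capable gene are the stronger explanation. Dominant units in
  sporadic families additionally re-impose the zero-frequency rule on
  their allele.
* **Sporadic families are scanned under all models** (dominant de novo,
  recessive homozygous, compound het, X-linked) — sporadic cases resolve
  through all of these mechanisms in practice.
* **Compound-het phasing.** Trans is confirmed when father and mother each
  carry exactly one allele of the pair, or when any unaffected sequenced
  direct relative carries exactly one; a pair both of whose alleles sit in
  one parent is rejected as cis. Singleton probands yield phase-unknown
  units, reported with that caveat. With more than two candidate alleles
  every surviving pair is reported, ranked by truncating-allele count and
  then by lower maximum reference MAF.
* **Segregation.** A unit is refuted only by an unaffected sequenced
  relative carrying the *full* causal genotype (both alleles of a pair,
  hom-alt for a homozygous unit, the allele itself for dominant, the
  hemizygous allele for X-linked males). Relatives of unknown affection
  can neither confirm nor refute. Heterozygous affected females in
  X-linked genes are emitted but flagged low-confidence.
* **Digenic pairs are advisory.** Two surviving monoallelic dominant units
  in different genes are flagged as a possible digenic pair without
  suppressing either unit; gene-level family counts count the family once
  per gene.
* **Rescue ceiling is external-only.** The rescue scan gates the in-house
  control frequency at the recessive 0.005 and applies `maf_rescue` to the
  external references only; folding the in-house count into the 0.001
  ceiling would make the two gates redundant at tight settings.
* **Short-circuit order QC → frequency → consequence → predictor**, with
  the trace recording the first failure — deterministic, auditable output.

## Bundled reference tables

The `rpscreen/data/` fixtures transcribe the mutation tables of a
98-family RP exome study (58 known-RP-gene rows over 40 families and 22
genes; 17 other-retinopathy rows over 11 families and 8 genes; 3 rescue
candidates), with the matching gene panels and the 12-entry
reported-mutation catalog. Transcription conventions: irregular predictor
tokens are mapped case-insensitively onto the closed vocabulary
("possibly neutral" → benign, "possibly deleterious" → possibly damaging);
one family label is printed two-digit (`RP-62`) and kept as printed; one
splice allele printed with an unmatched parenthesis is stored normalized.
The rescue table prints allele *counts* per source; allele numbers are
4040 for the 2020-individual in-house cohort, 5008 for the thousand-genome
reference, 121412 for the 60,706-exome reference, and the printed East
Asian allele numbers. Only MAF comparisons consume them. The
other-retinopathy panel's per-gene modes are not printed in the source
tables and are assigned from each gene's observed genotype configuration.

## The synthetic cohort generator

`synthetic_cohort.simulate_cohort` emulates the study design: 22 dominant
(trio or three-generation, one affected parent), 19 recessive (quartet
with an unaffected sibling), 52 sporadic (singleton with probability 0.7,
else trio) and 5 X-linked families (trio, affected son, carrier mother).
Per-stratum causal fractions default to the observed diagnostic yields
(0.59 / 0.42 / 0.31 / 0.80); the sporadic causal mechanism mix is
3/4 compound het, 1/8 homozygous, 1/8 de novo, matching the observed
12:2:2 split. Causal alleles are 40% truncating (no predictor calls) and
60% damaging missense; a `predictor_false_benign` rate flips each causal
missense verdict to benign independently.

Every non-causal variant is constructed to fail a named rule: per family,
one decoy per feasible rule class (low quality; common, AC ≥ 100/4040;
synonymous or noncoding; triple-benign missense; a causal-style genotype
shared with an unaffected relative; a cis het pair from one parent), plus
background variation (mean 150 variants per family) drawn from the
common / synonymous / noncoding / benign-missense classes with a
zero-inflated allele-count spectrum. Gene placement is bookkept so that
no recessive-capable gene accumulates an unintended trans-compatible rare
pair — this is what makes "sensitivity 1.0, zero leaks" provable rather
than probable on noise-free runs. Segregation and cis decoys require
informative relatives and are skipped in singleton families; every rule
class is still exercised at cohort level. Positions live on synthetic
contigs (one per gene, X-linked genes on `chrX`); no reference genome is
shipped or needed. Output is byte-deterministic under the config seed.

What the simulator deliberately does **not** emulate: rare damaging
missense background variation (real exomes contain benign-but-predicted-
damaging rare alleles; here they would be indistinguishable from implants,
so recovery on real data will always be below the synthetic 1.0),
linkage disequilibrium, realistic per-gene mutation rates, genotyping
error, and mosaicism. Passing recovery tests therefore demonstrates rule
correctness and composition, not real-world diagnostic yield. Likewise
the per-gene burden operation is exercised for arithmetic correctness on
synthetic counts; the bundled tables carry no cohort-wide variant lists,
so no real burden values are reproduced.

## Problem sizes and numerics

The bundled-table analyses are exact and effectively instantaneous. The
validation cohort is the full 98-family composition (~15,000 variants),
which the whole simulate → prioritize → evaluate loop completes in well
under a second; property tests run the cascade against a brute-force
per-rule oracle on 200-variant cohorts and enumerate all informative
parental genotype patterns for compound-het phasing. All frequency
comparisons are exact rational comparisons on AC/AN pairs evaluated in
double precision; thresholds are compared with `<=` / `>` exactly as
stated in the rule definitions, and an allele number of zero defines a
frequency of zero (no observation is not evidence of commonness).

## Known limitations

* Annotated input only; no VEP/ANNOVAR-equivalent, no liftover, no joint
  calling, no structural variants.
* Phasing uses pedigree logic only — no population-haplotype phasing.
* The fixture tables carry post-QC calls without quality/depth fields;
  in table mode the QC gate passes such records (logged), so QC behavior
  is exercised through VCF mode and simulation.
* The flat-table dialect records proband genotype configurations only;
  segregation, de novo and cis/trans rules need VCF+PED mode (or the
  in-memory API) to see relatives.
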