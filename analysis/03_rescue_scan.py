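"""Rescue scan: uncertain candidates among unsolved sporadic probands.

Heterozygous missense alleles in sporadic families can be over-excluded
by the strict dominant zero-frequency rule (an undiagnosed late-onset
carrier in the control set is enough to remove a true mutation).  This
pass re-admits heterozygous missense variants that are rare in-house
(<0.5%), called deleterious by PROVEAN and damaging by SIFT, and at or
below MAF 0.001 in the external references.  Writes
results/rescue/uncertain_candidates.tsv.
"""

from pathlib import Path

from rpscreen.filter_cascade import FilterPolicy, allele_frequency
from rpscreen.io_formats import (
    families_from_table,
    load_rescue_table,
    variants_by_family,
)
from rpscreen.reporting import rescue_scan, write_units_tsv

OUT = Path(__file__).resolve().parent.parent / "results" / "rescue"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = load_rescue_table()
    policy = FilterPolicy()
    units = rescue_scan(families_from_table(rows), variants_by_family(rows),
                        policy)
    write_units_tsv(units, OUT / "uncertain_candidates.tsv")

    lookup = {r.key: r for _, _, r, _ in rows}
    print(f"{len(units)} uncertain candidates "
          f"(rescue ceiling {policy.maf_rescue}):")
    for unit in units:
        variant = lookup[unit.variants[0]]
        worst = max(
            (allele_frequency(ac, an)
             for src, (ac, an) in variant.frequencies.items()
             if src != "in_house"), default=0.0)
        inhouse = allele_frequency(*variant.frequencies["in_house"])
        print(f"  {unit.family_id}  {unit.gene:7s} {variant.hgvs_c:11s} "
              f"{variant.hgvs_p:13s} in-house MAF {inhouse:.2e}, "
              f"max external MAF {worst:.2e}")


if __name__ == "__main__":
    main()
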