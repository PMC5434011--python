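"""Second-tier pass: mutations in other retinal-disease genes.

Families left unexplained by the known-RP panel are re-examined against a
broader retinopathy gene panel; units formed there are tiered
other_retinopathy_gene (they do not count toward the primary diagnostic
yield).  Writes results under results/other_retinopathy/.
"""

from pathlib import Path

from rpscreen.io_formats import (
    load_known_rp_panel,
    load_other_retinopathy_panel,
    load_other_retinopathy_table,
    load_reported_catalog,
)
from rpscreen.pipeline import prioritize_table
from rpscreen.reporting import write_units_tsv

OUT = Path(__file__).resolve().parent.parent / "results" / \
    "other_retinopathy"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = load_other_retinopathy_table()
    result = prioritize_table(
        rows, load_other_retinopathy_panel(), load_reported_catalog(),
        other_panel=load_other_retinopathy_panel(),
        known_panel=load_known_rp_panel(), cohort_size=98)
    write_units_tsv(result.units, OUT / "units.tsv")
    result.summary.to_json(OUT / "summary.json")

    s = result.summary
    print(f"{len(rows)} table rows -> {len(result.units)} units")
    print(f"{s.distinct_mutations} distinct mutations in "
          f"{s.n_families_with_units} families across "
          f"{s.distinct_genes} other-retinopathy genes")
    shared = [u for u in result.units if u.gene == "CYP4V2"]
    print(f"CYP4V2 (Bietti crystalline dystrophy gene): "
          f"{len({u.family_id for u in shared})} families")


if __name__ == "__main__":
    main()
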