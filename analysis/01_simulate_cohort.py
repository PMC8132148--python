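#!/usr/bin/env python
"""Generate the reference two-species cohort used by the downstream
analysis steps.

Writes standard-format inputs (VCF, GFF3, FASTA, sample sheet, genome
layout) plus truth files under results/cohort/.  The cohort carries the
domestication bottleneck (cultivar heterozygosity one third of
landrace2), a 2:1 A:D subgenome asymmetry, and species-diagnostic sites.
"""

from pathlib import Path

from cottonpop.sim import simulate_cohort, write_cohort
from cottonpop.studies import bottleneck_study

SEED = 1
OUT = Path("scratch/cohort")  # bulky cohort data; summaries go to results/


def main() -> None:
    cfg = bottleneck_study(SEED)
    table, sheet, annotation, layout, truth = simulate_cohort(cfg)
    paths = write_cohort(table, sheet, annotation, layout, truth, OUT)
    n_a = (table.sites["chrom"].map(layout.subgenome_map()) == "A").sum()
    n_d = table.n_sites - n_a
    print(f"cohort: {table.n_sites} sites x {table.n_samples} accessions, "
          f"{len(annotation.genes)} genes")
    print(f"subgenome site split A:D = {n_a}:{n_d} "
          f"(lengths {layout.table['length_bp'].tolist()})")
    print(f"diagnostic sites: {int(truth.frequencies['is_diagnostic'].sum())}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
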