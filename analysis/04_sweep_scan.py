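#!/usr/bin/env python
"""Selective-sweep scan on a cohort with planted sweeps.

Simulates the sweep-recovery cohort (20 Mb, 200 accessions, five 200-kb
regions where cultivar diversity is scaled to 0.2), runs the joint
top-5% pi-ratio x Fst scan with 100-kb/20-kb sliding windows, merges
selected windows into regions, summarizes them by subgenome, and checks
the detected regions against the planted truth with a 1000-permutation
overlap test.  Writes results under results/sweeps/.
"""

from pathlib import Path

from cottonpop.core import write_bed
from cottonpop.diversity import window_stats
from cottonpop.evaluation import sweep_recovery
from cottonpop.sim import simulate_cohort
from cottonpop.studies import sweep_study
from cottonpop.sweeps import (
    joint_top_quantile_scan,
    merge_selected_windows,
    overlap_permutation_test,
    subgenome_summary,
)
from cottonpop.variants import genes_in_intervals

SEED = 1
OUT = Path("results/sweeps")
DATA_OUT = Path("scratch/sweeps")


def main() -> None:
    table, sheet, annotation, layout, truth = simulate_cohort(sweep_study(SEED))
    lr2 = sheet.samples(species="sp1", population="landrace2")
    cul = sheet.samples(species="sp1", population="cultivar")
    windows = window_stats(table.snps(), lr2, cul, layout)
    OUT.mkdir(parents=True, exist_ok=True)
    DATA_OUT.mkdir(parents=True, exist_ok=True)
    windows.to_csv(DATA_OUT / "windows.tsv", sep="\t", index=False, float_format="%.6g")

    selected, thresholds = joint_top_quantile_scan(windows, q=0.05)
    regions = merge_selected_windows(selected, layout)
    gene_lists = genes_in_intervals(
        list(zip(regions["chrom"], regions["start"], regions["end"])), annotation
    )
    regions["n_genes"] = [len(g) for g in gene_lists]
    regions.to_csv(OUT / "regions.tsv", sep="\t", index=False, float_format="%.6g")
    write_bed(regions, OUT / "regions.bed")

    print(f"{len(windows)} windows scanned; thresholds: "
          f"pi_ratio >= {thresholds['pi_ratio']:.2f}, fst >= {thresholds['fst']:.3f}")
    print(f"{len(selected)} selected windows -> {len(regions)} sweep regions")
    print(subgenome_summary(regions, layout, annotation).to_string(index=False))

    rec = sweep_recovery(regions, truth.sweeps)
    print(f"recovery: {rec['n_recovered']}/{rec['n_truth']} planted sweeps hit")
    res = overlap_permutation_test(
        truth.sweeps, regions, layout, n_permutations=1000, seed=SEED
    )
    res.to_json(OUT / "overlap_vs_truth.json")
    print(f"overlap with truth: {res.observed_overlap_bp / 1e6:.2f} Mb, "
          f"permutation p = {res.p_value:.4g} (N={res.n_permutations})")


if __name__ == "__main__":
    main()
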