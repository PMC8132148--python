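#!/usr/bin/env python
"""Quality control of the cohort variants.

Reads results/cohort/ (step 01), removes samples with >25% missing
genotypes, then sites with >25% missing or minor-allele frequency below
5%, and classifies the surviving indels.  Writes the filtered VCF and an
indel classification table under results/qc/.
"""

from pathlib import Path

from cottonpop.core import GeneAnnotation, GenomeLayout, SampleSheet, read_variants
from cottonpop.variants import classify_indels, filter_samples_by_missing, filter_sites

IN = Path("scratch/cohort")
DATA_OUT = Path("scratch/qc")
OUT = Path("results/qc")


def main() -> None:
    layout = GenomeLayout.from_tsv(IN / "genome_layout.tsv")
    sheet = SampleSheet.from_tsv(IN / "samples.tsv")
    annotation = GeneAnnotation.from_gff3(IN / "annotation.gff3")
    table = read_variants(IN / "cohort.vcf", layout)
    print(f"input: {table.n_sites} sites x {table.n_samples} samples")

    table, sheet = filter_samples_by_missing(table, sheet, 0.25)
    before = table.n_sites
    table = filter_sites(table, layout, 0.25, 0.05)
    print(f"QC: {before - table.n_sites} sites removed "
          f"({table.n_sites} kept), {int(sheet.table['excluded'].sum())} samples excluded")

    DATA_OUT.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(parents=True, exist_ok=True)
    table.write_vcf(DATA_OUT / "filtered.vcf", layout)
    sheet.to_tsv(DATA_OUT / "samples_qc.tsv")

    indels = classify_indels(table, annotation, layout)
    indels.to_csv(OUT / "indel_classes.tsv", sep="\t", index=False)
    if len(indels):
        fs = indels["frameshift"].mean()
        print(f"indels: {len(indels)} kept, {fs:.0%} frameshift "
              f"(lengths not multiples of three)")


if __name__ == "__main__":
    main()
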