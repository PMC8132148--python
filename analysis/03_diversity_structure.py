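#!/usr/bin/env python
"""Diversity and population structure of the QC'd cohort.

Computes nucleotide diversity stratified by population x genomic feature
class x subgenome (the bottleneck table), fourfold-degenerate-site
diversity, Patterson-normalized PCA per species, and genome-wide
weighted Fst between the two species.  Writes tables under
results/diversity/.
"""

from pathlib import Path

from cottonpop.core import GeneAnnotation, GenomeLayout, SampleSheet, read_variants
from cottonpop.diversity import (
    fourfold_pi,
    pca_patterson,
    stratified_pi,
    wc_fst_components,
    weighted_fst,
)
from cottonpop.variants import (
    annotate_site_features,
    feature_class_lengths,
    find_fourfold_sites,
    paint_feature_classes,
)

COHORT = Path("scratch/cohort")
QC = Path("scratch/qc")
OUT = Path("results/diversity")


def main() -> None:
    layout = GenomeLayout.from_tsv(COHORT / "genome_layout.tsv")
    sheet = SampleSheet.from_tsv(QC / "samples_qc.tsv")
    annotation = GeneAnnotation.from_gff3(COHORT / "annotation.gff3")
    table = read_variants(QC / "filtered.vcf", layout)
    snp = table.snps()
    OUT.mkdir(parents=True, exist_ok=True)

    painted = paint_feature_classes(annotation, layout)
    feats = annotate_site_features(snp, annotation, layout, painted=painted)
    lengths = feature_class_lengths(painted, layout)
    strat = stratified_pi(snp, feats, lengths, sheet)
    strat.to_csv(OUT / "stratified_pi.tsv", sep="\t", index=False, float_format="%.6g")

    wide = strat[strat["subgenome"] == "all"].pivot_table(
        index="feature_class", columns="group", values="pi"
    )
    print("pi by feature class (x 1e-3):")
    print((wide * 1e3).round(3).to_string())
    ov = wide.loc["overall"]
    if {"sp1/cultivar", "sp1/landrace2"} <= set(ov.index):
        print(f"\nbottleneck: sp1 cultivar/landrace2 overall pi ratio = "
              f"{ov['sp1/cultivar'] / ov['sp1/landrace2']:.3f}")

    from cottonpop.core import read_fasta

    genome = read_fasta(COHORT / "genome.fa")
    fourfold = find_fourfold_sites(annotation, genome)
    for pop in ("wild", "cultivar"):
        ids = sheet.samples(species="sp1", population=pop)
        print(f"4D-site pi, sp1 {pop}: {fourfold_pi(snp, fourfold, ids):.2e} "
              f"({len(fourfold)} 4D positions)")

    for sp in ("sp1", "sp2"):
        ids = sheet.samples(species=sp)
        coords, frac = pca_patterson(snp, ids)
        coords.to_csv(OUT / f"pca_{sp}.tsv", sep="\t", float_format="%.6g")
        print(f"PCA {sp}: PC1 {frac[0]:.1%}, PC2 {frac[1]:.1%} of variance")

    comp = wc_fst_components(snp, sheet.samples(species="sp1"), sheet.samples(species="sp2"))
    print(f"weighted Fst between species: {weighted_fst(comp):.3f}")


if __name__ == "__main__":
    main()
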