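"""QC filtering and annotation: VCF parsing, the >25% missing / 5% MAF
rules, feature classification, codon degeneracy, and indel classes."""

import numpy as np
import pandas as pd
import pytest

from cottonpop.core import (
    Gene,
    GeneAnnotation,
    GenomeLayout,
    PipelineError,
    SampleSheet,
    VariantTable,
    read_variants,
)
from cottonpop.variants import (
    annotate_degeneracy,
    annotate_site_features,
    classify_indels,
    feature_class_lengths,
    filter_samples_by_missing,
    filter_sites,
    find_fourfold_sites,
    genes_in_intervals,
    paint_feature_classes,
    site_filter_mask,
)

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=Chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
Chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
Chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
Chr1\t300\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t1/1
"""


@pytest.fixture()
def toy_layout():
    return GenomeLayout.from_specs([("Chr1", 100_000, "A")])


class TestReadVariants:
    def test_triallelic_dropped_and_missing_decoded(self, tmp_path, toy_layout):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        table = read_variants(p, toy_layout)
        assert table.n_sites == 2  # triallelic record removed
        assert list(table.sites["pos"]) == [100, 300]
        assert table.genotypes[0].tolist() == [0, 1, 2]
        assert table.genotypes[1].tolist() == [-1, 1, 2]

    def test_unknown_chromosome_is_named_in_error(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        layout = GenomeLayout.from_specs([("Chr9", 100_000, "A")])
        with pytest.raises(PipelineError, match="Chr1"):
            read_variants(p, layout)

    def test_simulated_cohort_round_trips_through_vcf(self, tmp_path, demo_cohort):
        table, _, _, layout, _ = demo_cohort
        p = tmp_path / "cohort.vcf"
        table.write_vcf(p, layout)
        again = read_variants(p, layout)
        assert again.samples == table.samples
        pd.testing.assert_frame_equal(
            again.sites.astype({"indel_length": int}),
            table.sites.astype({"indel_length": int}),
        )
        assert np.array_equal(again.genotypes, table.genotypes)


class TestSampleFilter:
    def _table(self, missing_rates, n_sites=200):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(n_sites, len(missing_rates))).astype(np.int8)
        for j, rate in enumerate(missing_rates):
            k = int(round(rate * n_sites))
            geno[:k, j] = -1
        sites = pd.DataFrame(
            {"chrom": "Chr1", "pos": np.arange(1, n_sites + 1), "ref": "A",
             "alt": "G", "is_indel": False, "indel_length": 0}
        )
        samples = [f"s{j}" for j in range(len(missing_rates))]
        sheet = SampleSheet(pd.DataFrame(
            {"sample_id": samples, "species": "sp1", "population": "wild"}
        ))
        return VariantTable(sites, geno, samples), sheet

    def test_threshold_is_strict(self):
        table, sheet = self._table([0.30, 0.20, 0.25])
        out, sheet2 = filter_samples_by_missing(table, sheet, 0.25)
        assert out.samples == ["s1", "s2"]  # 30% removed, 20% and exactly 25% kept
        assert sheet2.table.loc[0, "excluded"]
        assert "missing" in sheet2.table.loc[0, "exclude_reason"]

    def test_scripted_rates_remove_exactly_two(self):
        table, sheet = self._table([0.10, 0.26, 0.50])
        out, _ = filter_samples_by_missing(table, sheet, 0.25)
        assert out.samples == ["s0"] or out.n_samples == 1

    def test_no_missing_is_identity(self):
        table, sheet = self._table([0.0, 0.0, 0.0])
        out, sheet2 = filter_samples_by_missing(table, sheet, 0.25)
        assert out.samples == table.samples
        assert not sheet2.table["excluded"].any()

    def test_all_removed_raises(self):
        table, sheet = self._table([0.9, 0.9])
        with pytest.raises(PipelineError):
            filter_samples_by_missing(table, sheet, 0.25)


class TestSiteFilter:
    def test_low_maf_site_removed(self, toy_layout):
        # alt count 1 of 40 alleles -> MAF 0.025 < 0.05
        geno = np.zeros((1, 20), dtype=np.int8)
        geno[0, 0] = 1
        sites = pd.DataFrame(
            {"chrom": ["Chr1"], "pos": [10], "ref": ["A"], "alt": ["G"],
             "is_indel": [False], "indel_length": [0]}
        )
        table = VariantTable(sites, geno, [f"s{i}" for i in range(20)])
        assert filter_sites(table, toy_layout).n_sites == 0

    def test_full_calls_maf_half_kept(self, toy_layout):
        geno = np.tile(np.array([[0, 2]], dtype=np.int8), (1, 10))
        sites = pd.DataFrame(
            {"chrom": ["Chr1"], "pos": [10], "ref": ["A"], "alt": ["G"],
             "is_indel": [False], "indel_length": [0]}
        )
        table = VariantTable(sites, geno, [f"s{i}" for i in range(20)])
        assert filter_sites(table, toy_layout).n_sites == 1

    def test_scripted_table_matches_brute_force_oracle(self, toy_layout, rng):
        n_sites, n_samples = 100, 30
        geno = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
        miss = rng.random((n_sites, n_samples)) < rng.uniform(0, 0.5, size=(n_sites, 1))
        geno[miss] = -1
        sites = pd.DataFrame(
            {"chrom": "Chr1", "pos": np.arange(1, n_sites + 1), "ref": "A",
             "alt": "G", "is_indel": False, "indel_length": 0}
        )
        table = VariantTable(sites, geno, [f"s{i}" for i in range(n_samples)])

        survivors = []  # independent per-row scan
        for i in range(n_sites):
            row = [g for g in geno[i] if g >= 0]
            if len(row) / n_samples < 0.75:
                continue
            alt = sum(row)
            f = alt / (2 * len(row))
            if min(f, 1 - f) < 0.05:
                continue
            survivors.append(i)
        out = filter_sites(table, toy_layout)
        assert out.n_sites == len(survivors)
        assert list(out.sites["pos"]) == [i + 1 for i in survivors]

    def test_documented_filter_order_contract(self, demo_cohort):
        """Samples-then-sites is the pipeline order; its output is stable."""
        table, sheet, _, layout, _ = demo_cohort
        t1, _ = filter_samples_by_missing(table, sheet)
        t1 = filter_sites(t1, layout)
        t2, _ = filter_samples_by_missing(table, sheet)
        t2 = filter_sites(t2, layout)
        assert np.array_equal(t1.genotypes, t2.genotypes)


def template_annotation():
    """Two genes on Chr1: one + strand, one - strand (mirrored template)."""
    plus = Gene(
        "gP", "Chr1", "+", 10_001, 11_500,
        exons=((10_001, 10_500), (11_001, 11_500)),
        cds=((10_201, 10_500), (11_001, 11_300)),
        utr5=((10_001, 10_200),), utr3=((11_301, 11_500),),
    )
    minus = Gene(
        "gM", "Chr1", "-", 30_001, 31_500,
        exons=((30_001, 30_500), (31_001, 31_500)),
        cds=((30_201, 30_500), (31_001, 31_300)),
        utr5=((31_301, 31_500),), utr3=((30_001, 30_200),),
    )
    return GeneAnnotation([plus, minus])


class TestFeatureClassification:
    layout = GenomeLayout.from_specs([("Chr1", 100_000, "A")])

    def _classify(self, positions):
        sites = pd.DataFrame(
            {"chrom": "Chr1", "pos": positions, "ref": "A", "alt": "G",
             "is_indel": False, "indel_length": 0}
        )
        table = VariantTable(sites, np.zeros((len(positions), 2), np.int8), ["a", "b"])
        return annotate_site_features(table, template_annotation(), self.layout)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_300, "exon"),      # CDS of + gene
            (10_100, "5utr"),
            (11_400, "3utr"),
            (10_700, "intron"),
            (10_000, "upstream"),  # 1 bp before + TSS
            (11_501, "downstream"),
            (5_000, "intergenic"),
            (31_501, "upstream"),  # 1 bp past the - gene end = upstream
            (30_000, "downstream"),
            (31_400, "5utr"),      # mirrored UTRs on - strand
            (30_100, "3utr"),
        ],
    )
    def test_strand_aware_classes(self, pos, expected):
        out = self._classify([pos])
        assert out["feature_class"].iloc[0] == expected

    def test_random_sites_match_per_base_interval_oracle(self, rng):
        ann = template_annotation()
        positions = sorted(rng.choice(np.arange(1, 40_000), size=50, replace=False))
        out = self._classify(list(positions))

        def oracle(pos):  # explicit interval scan, priority high -> low
            for g in ann.genes:
                for s, e in g.utr5:
                    if s <= pos <= e:
                        return "5utr"
                for s, e in g.utr3:
                    if s <= pos <= e:
                        return "3utr"
            for g in ann.genes:
                for s, e in g.cds:
                    if s <= pos <= e:
                        return "exon"
            for g in ann.genes:
                if g.start <= pos <= g.end:
                    return "intron"
            for g in ann.genes:
                lo, hi = (g.start - 5000, g.start - 1) if g.strand == "+" else (g.end + 1, g.end + 5000)
                if lo <= pos <= hi:
                    return "upstream"
            for g in ann.genes:
                lo, hi = (g.end + 1, g.end + 5000) if g.strand == "+" else (g.start - 5000, g.start - 1)
                if lo <= pos <= hi:
                    return "downstream"
            return "intergenic"

        expected = [oracle(p) for p in positions]
        assert list(out["feature_class"]) == expected

    def test_classes_partition_sites_and_lengths_sum(self):
        painted = paint_feature_classes(template_annotation(), self.layout)
        lengths = feature_class_lengths(painted, self.layout)
        assert lengths["length_bp"].sum() == 100_000
        out = self._classify(list(range(9_000, 12_000, 37)))
        assert out["feature_class"].notna().all()


class TestFourfold:
    def _single_gene(self, cds_seq, strand="+"):
        # gene: CDS occupies 101..(100+len) on Chr1
        L = len(cds_seq)
        g = Gene("g1", "Chr1", strand, 101, 100 + L,
                 exons=((101, 100 + L),), cds=((101, 100 + L),),
                 utr5=(), utr3=())
        seq = "T" * 100 + (cds_seq if strand == "+" else _rc(cds_seq)) + "A" * 100
        return GeneAnnotation([g]), {"Chr1": seq}

    def test_glycine_third_position_is_4d(self):
        ann, genome = self._single_gene("GGA" * 4)
        sites = find_fourfold_sites(ann, genome)
        assert sites == {("Chr1", 103), ("Chr1", 106), ("Chr1", 109), ("Chr1", 112)}

    def test_tryptophan_has_no_4d_site(self):
        ann, genome = self._single_gene("TGGTGGTGG")
        assert find_fourfold_sites(ann, genome) == set()

    def test_minus_strand_codons_reconstructed(self):
        # GGA codons on - strand: genomic sequence is revcomp
        ann, genome = self._single_gene("GGA" * 3, strand="-")
        # translation order is genomic-descending; third codon positions
        # are genomic positions 107, 104, 101
        assert find_fourfold_sites(ann, genome) == {
            ("Chr1", 107), ("Chr1", 104), ("Chr1", 101)
        }

    def test_internal_stop_skips_gene(self):
        ann, genome = self._single_gene("GGATAAGGA")
        assert find_fourfold_sites(ann, genome) == set()

    def test_simulated_cds_matches_codon_table_enumeration(self, demo_cohort):
        from Bio.Data.CodonTable import standard_dna_table

        table, _, ann, _, _ = demo_cohort
        from cottonpop.sim import sequences_as_strings

        genome = sequences_as_strings(table)
        got = find_fourfold_sites(ann, genome)
        fwd = dict(standard_dna_table.forward_table)

        expected = set()  # independent enumeration over every CDS codon
        for g in ann.genes[:40]:
            pos = []
            for s, e in g.cds:
                pos.extend(range(s, e + 1))
            seq = "".join(genome[g.chrom][p - 1] for p in pos)
            if g.strand == "-":
                pos = pos[::-1]
                seq = _rc(seq)
            for i in range(0, len(seq) - 2, 3):
                fam = {fwd.get(seq[i : i + 2] + b) for b in "ACGT"}
                if len(fam) == 1 and None not in fam:
                    expected.add((g.chrom, pos[i + 2]))
        covered = {
            (g.chrom, p)
            for g in ann.genes[:40]
            for s, e in g.cds
            for p in range(s, e + 1)
        }
        assert {k for k in got if k in covered} == expected

    def test_output_is_subset_of_cds_third_positions(self, demo_cohort):
        table, _, ann, _, _ = demo_cohort
        from cottonpop.sim import sequences_as_strings

        got = find_fourfold_sites(ann, sequences_as_strings(table))
        thirds = set()
        for g in ann.genes:
            pos = []
            for s, e in g.cds:
                pos.extend(range(s, e + 1))
            if g.strand == "-":
                pos = pos[::-1]
            thirds.update((g.chrom, p) for p in pos[2::3])
        assert got <= thirds


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestIndels:
    def test_lengths_one_to_nine_give_six_frameshifts(self):
        layout = GenomeLayout.from_specs([("Chr1", 100_000, "A")])
        sites = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos": np.arange(1000, 1000 + 9 * 50, 50),
                "ref": "A",
                "alt": "G",
                "is_indel": True,
                "indel_length": [1, -2, 3, 4, -5, 6, 7, -8, 9],
            }
        )
        table = VariantTable(sites, np.ones((9, 2), np.int8), ["a", "b"])
        out = classify_indels(table, template_annotation(), layout)
        assert out["frameshift"].sum() == 6
        assert (~out["frameshift"]).sum() == 3
        assert list(out["length_class"]) == ["1-3"] * 3 + ["4-9"] * 6

    def test_in_frame_deletion_and_frameshift_insertion(self):
        layout = GenomeLayout.from_specs([("Chr1", 100_000, "A")])
        sites = pd.DataFrame(
            {"chrom": ["Chr1", "Chr1"], "pos": [100, 200],
             "ref": ["ACCC", "A"], "alt": ["A", "AG"],
             "is_indel": [True, True], "indel_length": [-3, 1]}
        )
        table = VariantTable(sites, np.ones((2, 2), np.int8), ["a", "b"])
        out = classify_indels(table, template_annotation(), layout)
        assert not out["frameshift"].iloc[0]  # length-3 deletion in frame
        assert out["frameshift"].iloc[1]      # 1-bp insertion shifts frame


class TestGenesInIntervals:
    def test_full_gene_and_intergenic_gap(self):
        ann = template_annotation()
        got = genes_in_intervals([("Chr1", 9_000, 12_000), ("Chr1", 50_000, 60_000)], ann)
        assert got == [["gP"], []]

    def test_random_intervals_match_brute_force(self, rng):
        ann = template_annotation()
        ivals = []
        for _ in range(20):
            s = int(rng.integers(1, 40_000))
            ivals.append(("Chr1", s, s + int(rng.integers(1, 5_000))))
        got = genes_in_intervals(ivals, ann)
        for (c, s, e), lst in zip(ivals, got):
            expected = sorted(
                g.gene_id for g in ann.genes
                if g.chrom == c and not (e < g.start or s > g.end)
            )
            assert lst == expected


class TestDegeneracy:
    def test_substitution_classes(self):
        # CDS = GGA TGG -> pos 103 is 4D; TGG (Trp) third position is 0-fold
        ann = GeneAnnotation([
            Gene("g1", "Chr1", "+", 101, 106,
                 exons=((101, 106),), cds=((101, 106),), utr5=(), utr3=())
        ])
        genome = {"Chr1": "T" * 100 + "GGATGG" + "A" * 100}
        sites = pd.DataFrame(
            {"chrom": ["Chr1"] * 3, "pos": [103, 106, 50],
             "ref": ["A", "G", "T"], "alt": ["G", "A", "C"],
             "is_indel": [False] * 3, "indel_length": [0] * 3}
        )
        table = VariantTable(sites, np.zeros((3, 2), np.int8), ["a", "b"])
        out = annotate_degeneracy(table, ann, genome)
        assert list(out) == ["fourfold", "nonsynonymous", "noncoding"]
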