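"""Core data containers and standard-format I/O.

The analysis operates on four in-memory objects:

``VariantTable``
    biallelic SNP/indel sites with an alt-allele dosage matrix (samples in
    columns, ``-1`` encoding a missing genotype),
``SampleSheet``
    per-accession species and population-class labels,
``GenomeLayout``
    chromosome lengths and A/D subgenome assignment of the allotetraploid,
``GeneAnnotation``
    gene models with exon/CDS/UTR structure (1-based inclusive coordinates).

Readers use cyvcf2 (VCF) and gffutils (GFF3).  Writers emit plain,
deterministic text so that a rerun with the same seed is byte-identical;
BED output converts the internal 1-based inclusive intervals to 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("cottonpop")

MISSING = -1  # dosage code for an uncalled genotype

SPECIES = ("sp1", "sp2")
POPULATIONS = ("wild", "landrace1", "landrace2", "cultivar")

_GT_STRINGS = np.array(["./.", "0/0", "0/1", "1/1"])  # index = dosage + 1


class PipelineError(RuntimeError):
    """Raised for contract violations detected at stage boundaries."""


# ---------------------------------------------------------------------------
# GenomeLayout


@dataclass
class GenomeLayout:
    """Chromosome lengths and subgenome (A or D) labels."""

    table: pd.DataFrame  # columns: chrom, length_bp, subgenome

    def __post_init__(self) -> None:
        required = {"chrom", "length_bp", "subgenome"}
        if not required.issubset(self.table.columns):
            raise PipelineError(f"layout needs columns {sorted(required)}")
        if self.table["chrom"].duplicated().any():
            raise PipelineError("duplicate chromosome in layout")
        bad = set(self.table["subgenome"]) - {"A", "D"}
        if bad:
            raise PipelineError(f"unknown subgenome labels: {sorted(bad)}")
        if (self.table["length_bp"] <= 0).any():
            raise PipelineError("non-positive chromosome length")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_specs(cls, specs: Sequence[tuple[str, int, str]]) -> "GenomeLayout":
        return cls(pd.DataFrame(specs, columns=["chrom", "length_bp", "subgenome"]))

    @property
    def chroms(self) -> list[str]:
        return list(self.table["chrom"])

    def length(self, chrom: str) -> int:
        row = self.table.loc[self.table["chrom"] == chrom, "length_bp"]
        if row.empty:
            raise PipelineError(f"chromosome {chrom!r} not in layout")
        return int(row.iloc[0])

    def subgenome(self, chrom: str) -> str:
        row = self.table.loc[self.table["chrom"] == chrom, "subgenome"]
        if row.empty:
            raise PipelineError(f"chromosome {chrom!r} not in layout")
        return str(row.iloc[0])

    def subgenome_map(self) -> dict[str, str]:
        return dict(zip(self.table["chrom"], self.table["subgenome"]))

    @property
    def total_length(self) -> int:
        return int(self.table["length_bp"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Per-sample species / population-class assignments.

    ``excluded`` samples stay in the sheet (with a reason) but are dropped
    from the genotype matrix by the QC stage.
    """

    table: pd.DataFrame  # sample_id, species, population, excluded, exclude_reason

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclude_reason" not in t.columns:
            t["exclude_reason"] = ""
        t["exclude_reason"] = t["exclude_reason"].fillna("")
        if t["sample_id"].duplicated().any():
            raise PipelineError("duplicate sample_id in sample sheet")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(
        self,
        species: str | None = None,
        population: str | None = None,
        include_excluded: bool = False,
    ) -> list[str]:
        t = self.table
        if not include_excluded:
            t = t[~t["excluded"]]
        if species is not None:
            t = t[t["species"] == species]
        if population is not None:
            t = t[t["population"] == population]
        return list(t["sample_id"])

    def exclude(self, sample_ids: Iterable[str], reason: str) -> "SampleSheet":
        t = self.table.copy()
        mask = t["sample_id"].isin(list(sample_ids))
        t.loc[mask, "excluded"] = True
        t.loc[mask, "exclude_reason"] = reason
        return SampleSheet(t)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(t)


# ---------------------------------------------------------------------------
# VariantTable


@dataclass
class VariantTable:
    """Sites plus an alt-dosage genotype matrix (n_sites x n_samples, int8).

    Sites are sorted by (chrom, pos); SNP records are biallelic; dosages are
    in {0, 1, 2} with ``-1`` for missing.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt, is_indel, indel_length
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise PipelineError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise PipelineError(f"samples not in table: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "VariantTable":
        idx = self.sample_indices(sample_ids)
        return VariantTable(self.sites.copy(), self.genotypes[:, idx], list(sample_ids))

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            list(self.samples),
        )

    def snps(self) -> "VariantTable":
        return self.subset_sites(~self.sites["is_indel"].to_numpy())

    # -- VCF ---------------------------------------------------------------

    def write_vcf(self, path: str | Path, layout: GenomeLayout | None = None) -> None:
        """Write a minimal deterministic VCFv4.2 (GT-only)."""
        lines = ["##fileformat=VCFv4.2"]
        if layout is not None:
            for _, row in layout.table.iterrows():
                lines.append(f"##contig=<ID={row['chrom']},length={row['length_bp']}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples)
        )
        gt = _GT_STRINGS[self.genotypes.astype(np.int16) + 1]
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        for i in range(self.n_sites):
            lines.append(
                f"{chroms[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt[i])
            )
        Path(path).write_text("\n".join(lines) + "\n")


def read_variants(vcf_path: str | Path, layout: GenomeLayout) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Multi-allelic records are dropped (count logged).  Genotypes become alt
    dosages; half-calls and missing GTs map to ``-1``.  A record on a
    chromosome absent from the layout is an error (it names the chromosome).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    known = set(layout.chroms)
    rows = []
    dosages = []
    n_multi = 0
    # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if v.CHROM not in known:
            raise PipelineError(
                f"VCF record on chromosome {v.CHROM!r} absent from genome layout"
            )
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        rows.append((v.CHROM, v.POS, ref, alt, len(ref) != len(alt), len(alt) - len(ref)))
        dosages.append(remap[np.clip(v.gt_types, 0, 3)])
    if n_multi:
        log.info("dropped %d multi-allelic records", n_multi)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "is_indel", "indel_length"]
    )
    geno = (
        np.vstack(dosages)
        if dosages
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    table = VariantTable(sites, geno, samples)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy())) if len(sites) else []
    if len(sites) and not np.array_equal(order, np.arange(len(sites))):
        table = VariantTable(
            sites.iloc[order].reset_index(drop=True), geno[order], samples
        )
    return table


# ---------------------------------------------------------------------------
# GeneAnnotation


Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]


@dataclass
class GeneAnnotation:
    """Gene models; CDS and UTR intervals are subsets of exons, CDS length
    per gene is a multiple of 3 (validated)."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            cds_len = sum(e - s + 1 for s, e in g.cds)
            if g.cds and cds_len % 3 != 0:
                raise PipelineError(f"gene {g.gene_id}: CDS length {cds_len} not divisible by 3")
            if g.strand not in "+-":
                raise PipelineError(f"gene {g.gene_id}: bad strand {g.strand!r}")

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    # -- GFF3 --------------------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes:
            tid = f"{g.gene_id}.t1"
            lines.append(
                f"{g.chrom}\tcottonpop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
            )
            lines.append(
                f"{g.chrom}\tcottonpop\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}"
            )
            for feat, ivals in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                frame_col = "0" if feat == "CDS" else "."
                for s, e in ivals:
                    lines.append(
                        f"{g.chrom}\tcottonpop\t{feat}\t{s}\t{e}\t.\t{g.strand}\t{frame_col}\t"
                        f"Parent={tid}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for g in db.features_of_type("gene"):
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(g.id):
                ival = (child.start, child.end)
                if child.featuretype == "exon":
                    exons.append(ival)
                elif child.featuretype == "CDS":
                    cds.append(ival)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(ival)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(ival)
            genes.append(
                Gene(
                    gene_id=g.id,
                    chrom=g.seqid,
                    strand=g.strand,
                    start=g.start,
                    end=g.end,
                    exons=tuple(sorted(exons)),
                    cds=tuple(sorted(cds)),
                    utr5=tuple(sorted(utr5)),
                    utr3=tuple(sorted(utr3)),
                )
            )
        genes.sort(key=lambda g: (g.chrom, g.start))
        return cls(genes)


# ---------------------------------------------------------------------------
# FASTA + BED helpers


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals: pd.DataFrame, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
    """Write 1-based inclusive (chrom, start, end [, extra]) rows as BED
    (0-based half-open)."""
    out = intervals.copy()
    out["bed_start"] = out["start"].astype(int) - 1
    out["bed_end"] = out["end"].astype(int)
    cols = ["chrom", "bed_start", "bed_end", *extra_cols]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, extra_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Read BED into 1-based inclusive chrom/start/end (+ named extras)."""
    names = ["chrom", "bed_start", "bed_end", *extra_cols]
    try:
        t = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        t = pd.DataFrame({n: pd.Series(dtype=(str if n == "chrom" else int)) for n in names})
    t["start"] = t["bed_start"] + 1
    t["end"] = t["bed_end"]
    return t.drop(columns=["bed_start", "bed_end"])
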