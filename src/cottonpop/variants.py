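"""Variant QC and annotation.

Implements the filtering and classification layer between raw biallelic
calls and the population-genetic statistics:

* sample removal at >25% missing genotypes, then site filtering at >25%
  missing and <5% minor-allele frequency (MAF on called alleles only);
* genomic-feature classification of each site into one of
  {intergenic, upstream, downstream, 5utr, exon, intron, 3utr} with the
  priority 5utr/3utr > exon(CDS) > intron > upstream > downstream >
  intergenic, strand-aware flanks (default 5 kb);
* fourfold-degenerate (4D) site discovery from CDS codons;
* small-indel classification (length class, frameshift = |len| mod 3 != 0);
* gene/interval overlap queries.

Feature classification paints one int8 array per chromosome in increasing
priority order, so site lookup and per-class base counts (the denominators
of stratified diversity) come from the same assignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    Gene,
    GeneAnnotation,
    GenomeLayout,
    PipelineError,
    SampleSheet,
    VariantTable,
    log,
)

FEATURE_CLASSES = (
    "intergenic",
    "downstream",
    "upstream",
    "intron",
    "exon",
    "5utr",
    "3utr",
)  # index order == painting order == ascending priority

_CLASS_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}


# ---------------------------------------------------------------------------
# QC filters


def missing_rate_per_sample(table: VariantTable) -> pd.Series:
    if table.n_sites == 0:
        return pd.Series(0.0, index=table.samples)
    rate = (table.genotypes == MISSING).mean(axis=0)
    return pd.Series(rate, index=table.samples)


def filter_samples_by_missing(
    table: VariantTable, sheet: SampleSheet, threshold: float = 0.25
) -> tuple[VariantTable, SampleSheet]:
    """Drop samples whose missing-genotype fraction exceeds ``threshold``.

    Exclusions are recorded on the returned sheet with the observed rate.
    """
    if not 0 < threshold <= 1:
        raise PipelineError(f"threshold must be in (0, 1], got {threshold}")
    rates = missing_rate_per_sample(table)
    dropped = rates.index[rates > threshold].tolist()
    if len(dropped) == table.n_samples:
        raise PipelineError("all samples exceed the missing-rate threshold")
    kept = [s for s in table.samples if s not in set(dropped)]
    sheet = sheet.exclude(
        dropped, f"missing genotype rate > {threshold:g}"
    )
    if dropped:
        log.info("removed %d samples for missingness > %g", len(dropped), threshold)
    return table.subset_samples(kept), sheet


def site_filter_mask(
    table: VariantTable,
    layout: GenomeLayout,
    max_missing: float = 0.25,
    min_maf: float = 0.05,
) -> np.ndarray:
    """Boolean keep-mask for :func:`filter_sites` (exposed for testing)."""
    called = table.genotypes != MISSING
    n_called = called.sum(axis=1)
    call_frac = n_called / max(table.n_samples, 1)
    alt = np.where(called, table.genotypes, 0).sum(axis=1)
    n_alleles = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(f, 1.0 - f)
    on_layout = table.sites["chrom"].isin(layout.chroms).to_numpy()
    return (call_frac >= 1.0 - max_missing) & (maf >= min_maf) & on_layout


def filter_sites(
    table: VariantTable,
    layout: GenomeLayout,
    max_missing: float = 0.25,
    min_maf: float = 0.05,
) -> VariantTable:
    """Keep sites with call fraction >= 1 - max_missing and MAF >= min_maf
    (computed over called alleles), restricted to layout chromosomes."""
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0 < v < 1:
            raise PipelineError(f"{name} must be in (0, 1), got {v}")
    keep = site_filter_mask(table, layout, max_missing, min_maf)
    out = table.subset_sites(keep)
    if out.n_sites == 0:
        log.warning("no sites survive QC filters")
    return out


# ---------------------------------------------------------------------------
# Feature classification


def _flank_intervals(g: Gene, flank_bp: int, chrom_len: int):
    """(upstream, downstream) 1-based inclusive intervals, strand-aware."""
    if g.strand == "+":
        up = (max(1, g.start - flank_bp), g.start - 1)
        down = (g.end + 1, min(chrom_len, g.end + flank_bp))
    else:
        up = (g.end + 1, min(chrom_len, g.end + flank_bp))
        down = (max(1, g.start - flank_bp), g.start - 1)
    return up, down


def paint_feature_classes(
    annotation: GeneAnnotation,
    layout: GenomeLayout,
    flank_bp: int = 5000,
) -> dict[str, np.ndarray]:
    """Per-chromosome int8 arrays of feature-class codes (0-based index =
    pos - 1).  Painted in ascending priority so overlaps resolve to the
    highest-priority class."""
    arrays = {
        chrom: np.zeros(layout.length(chrom), dtype=np.int8)
        for chrom in layout.chroms
    }
    by_chrom = annotation.by_chrom()
    for chrom, arr in arrays.items():
        genes = by_chrom.get(chrom, [])
        L = len(arr)
        layers: dict[str, list[tuple[int, int]]] = {c: [] for c in FEATURE_CLASSES[1:]}
        for g in genes:
            up, down = _flank_intervals(g, flank_bp, L)
            if down[0] <= down[1]:
                layers["downstream"].append(down)
            if up[0] <= up[1]:
                layers["upstream"].append(up)
            layers["intron"].append((g.start, g.end))
            layers["exon"].extend(g.exons)  # pre-paint exon extent
            layers["exon"].extend(g.cds)
            layers["5utr"].extend(g.utr5)
            layers["3utr"].extend(g.utr3)
        for cls in FEATURE_CLASSES[1:]:
            code = _CLASS_CODE[cls]
            for s, e in layers[cls]:
                s = max(1, s)
                e = min(L, e)
                if s <= e:
                    arr[s - 1 : e] = code
    return arrays


def feature_class_lengths(
    painted: Mapping[str, np.ndarray], layout: GenomeLayout
) -> pd.DataFrame:
    """Base counts per (chrom, feature_class) from painted arrays."""
    rows = []
    for chrom, arr in painted.items():
        counts = np.bincount(arr, minlength=len(FEATURE_CLASSES))
        for cls, n in zip(FEATURE_CLASSES, counts):
            rows.append((chrom, layout.subgenome(chrom), cls, int(n)))
    return pd.DataFrame(rows, columns=["chrom", "subgenome", "feature_class", "length_bp"])


def annotate_site_features(
    table: VariantTable,
    annotation: GeneAnnotation,
    layout: GenomeLayout,
    flank_bp: int = 5000,
    painted: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Classify every site into exactly one feature class.

    Returns a frame aligned with ``table.sites`` carrying ``feature_class``
    and ``subgenome``.  Sites on chromosomes without genes fall out as
    intergenic.
    """
    if painted is None:
        painted = paint_feature_classes(annotation, layout, flank_bp)
    annotated_chroms = set(annotation.by_chrom())
    classes = np.empty(table.n_sites, dtype=object)
    sub = np.empty(table.n_sites, dtype=object)
    submap = layout.subgenome_map()
    for chrom, idx in table.sites.groupby("chrom", sort=False).groups.items():
        pos = table.sites.loc[idx, "pos"].to_numpy()
        arr = painted[chrom]
        codes = arr[pos - 1]
        classes[idx] = np.array(FEATURE_CLASSES, dtype=object)[codes]
        sub[idx] = submap[chrom]
        if chrom not in annotated_chroms:
            log.info("chromosome %s has no annotated genes; sites are intergenic", chrom)
    return pd.DataFrame(
        {"chrom": table.sites["chrom"], "pos": table.sites["pos"],
         "feature_class": classes, "subgenome": sub}
    )


# ---------------------------------------------------------------------------
# Codon degeneracy

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON = _codon_table()


def _cds_positions(g: Gene) -> list[int]:
    """Genomic positions of the coding sequence in translation order."""
    pos: list[int] = []
    for s, e in g.cds:
        pos.extend(range(s, e + 1))
    if g.strand == "-":
        pos.reverse()
    return pos


def _cds_sequence(g: Gene, seq: str) -> str:
    raw = "".join(seq[s - 1 : e] for s, e in g.cds).upper()
    return _revcomp(raw) if g.strand == "-" else raw


def find_fourfold_sites(
    annotation: GeneAnnotation, genome: Mapping[str, str]
) -> set[tuple[str, int]]:
    """Third-codon genomic positions whose codon family is fourfold
    degenerate under the standard genetic code.

    Genes with an internal stop codon are skipped with a warning; a
    terminal stop is tolerated (its third position is never 4D).
    """
    fourfold: set[tuple[str, int]] = set()
    for g in annotation.genes:
        if not g.cds:
            continue
        cds = _cds_sequence(g, genome[g.chrom])
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(_CODON.get(c) == "*" for c in codons[:-1]):
            log.warning("gene %s has an internal stop codon; skipped", g.gene_id)
            continue
        positions = _cds_positions(g)
        for ci, codon in enumerate(codons):
            aa = {_CODON.get(codon[:2] + b) for b in "ACGT"}
            if len(aa) == 1 and "*" not in aa and None not in aa:
                fourfold.add((g.chrom, positions[3 * ci + 2]))
    return fourfold


def annotate_degeneracy(
    table: VariantTable,
    annotation: GeneAnnotation,
    genome: Mapping[str, str],
) -> pd.Series:
    """Per-site degeneracy class of the observed substitution:
    fourfold / synonymous_non4D / nonsynonymous for CDS SNPs, noncoding
    otherwise (indels and non-CDS sites)."""
    fourfold = find_fourfold_sites(annotation, genome)
    # map genomic position -> (gene, cds index)
    site_lookup: dict[tuple[str, int], tuple[Gene, int]] = {}
    for g in annotation.genes:
        for i, p in enumerate(_cds_positions(g)):
            site_lookup.setdefault((g.chrom, p), (g, i))
    out = []
    for chrom, pos, ref, alt, is_indel in zip(
        table.sites["chrom"], table.sites["pos"], table.sites["ref"],
        table.sites["alt"], table.sites["is_indel"],
    ):
        key = (chrom, int(pos))
        if is_indel or key not in site_lookup:
            out.append("noncoding")
            continue
        if key in fourfold:
            out.append("fourfold")
            continue
        g, i = site_lookup[key]
        cds = _cds_sequence(g, genome[g.chrom])
        ref_b, alt_b = str(ref).upper(), str(alt).upper()
        if g.strand == "-":
            ref_b, alt_b = _revcomp(ref_b), _revcomp(alt_b)
        ci, off = divmod(i, 3)
        codon = cds[3 * ci : 3 * ci + 3]
        mutant = codon[:off] + alt_b + codon[off + 1 :]
        same = _CODON.get(codon) == _CODON.get(mutant)
        out.append("synonymous_non4D" if same else "nonsynonymous")
    return pd.Series(out, index=table.sites.index, name="degeneracy_class")


# ---------------------------------------------------------------------------
# Indels


def classify_indels(
    table: VariantTable,
    annotation: GeneAnnotation,
    layout: GenomeLayout,
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Length class (1-3 vs 4-9 bp), frameshift potential, and feature
    placement of each indel (feature taken at the anchor position)."""
    idx = table.sites.index[table.sites["is_indel"]]
    sub = table.subset_sites(table.sites["is_indel"].to_numpy())
    feats = annotate_site_features(sub, annotation, layout, flank_bp)
    lengths = sub.sites["indel_length"].abs().astype(int)
    return pd.DataFrame(
        {
            "chrom": sub.sites["chrom"].to_numpy(),
            "pos": sub.sites["pos"].to_numpy(),
            "indel_length": sub.sites["indel_length"].to_numpy(),
            "length_class": np.where(lengths <= 3, "1-3", "4-9"),
            "frameshift": (lengths % 3 != 0).to_numpy(),
            "feature_class": feats["feature_class"].to_numpy(),
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# Interval / gene overlap


def genes_in_intervals(
    intervals: Sequence[tuple[str, int, int]], annotation: GeneAnnotation
) -> list[list[str]]:
    """Gene ids whose span overlaps each (chrom, start, end) interval by
    >= 1 bp (1-based inclusive intervals)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start : g.end + 1] = g.gene_id
    out = []
    for chrom, start, end in intervals:
        tree = trees.get(chrom)
        if tree is None:
            out.append([])
        else:
            out.append(sorted(iv.data for iv in tree.overlap(start, end + 1)))
    return out
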