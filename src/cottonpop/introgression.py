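"""Interspecific introgression inference from species-diagnostic SNPs.

A site is species-diagnostic when, among called alleles, one allele is at
frequency >= 0.95 in species 1's wild panel and the other at >= 0.95 in
species 2's wild panel, with call rate >= 0.8 in both panels (both
thresholds configurable; min_freq below strict fixation tolerates rare
panel miscalls).

Per accession, each diagnostic genotype is classified as donor-supporting
(carries >= 1 donor allele by default; a strict homozygous-donor mode is
available) or recipient-homozygous.  Maximal runs of donor-supporting
sites, uninterrupted by recipient-homozygous sites (missing genotypes are
skipped), become candidate segments when they contain >= 3 supporting
sites and span >= 500 bp — the genotype-level analog of the original
read-depth criteria (evidence depth + physical span).  Segment ends are
placed at the midpoint between the bounding supporting site and the
adjacent opposing diagnostic site (the unbiased breakpoint estimate;
``boundary="sites"`` restricts segments to the supporting-site span).
Adjacent segments with a gap strictly below 30 kb merge; accessions whose
summed segments exceed 10% of the genome are flagged as recent hybrids
and excluded from population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GeneAnnotation,
    GenomeLayout,
    PipelineError,
    SampleSheet,
    VariantTable,
)
from .variants import genes_in_intervals

SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "n_sites", "donor", "subgenome",
]


@dataclass
class DiagnosticIndex:
    """Species-diagnostic sites: which allele (as alt dosage 0 or 2 of the
    homozygote) belongs to each species, plus the thresholds used."""

    sites: pd.DataFrame  # chrom, pos, site_index, allele_sp1, allele_sp2
    panel_sizes: tuple[int, int]
    min_freq: float
    min_called: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def build_diagnostic_index(
    table: VariantTable,
    wild_panel_sp1: Sequence[str],
    wild_panel_sp2: Sequence[str],
    min_freq: float = 0.95,
    min_called: float = 0.8,
) -> DiagnosticIndex:
    """Infer SNPs that distinguish the two species from their wild panels."""
    p1 = list(wild_panel_sp1)
    p2 = list(wild_panel_sp2)
    if not p1 or not p2:
        raise PipelineError("wild panels must be non-empty")
    if set(p1) & set(p2):
        raise PipelineError("wild panels overlap")
    if len(p1) < 2 or len(p2) < 2:
        raise PipelineError("each wild panel needs >= 2 samples")

    def _panel(ids):
        g = table.genotypes[:, table.sample_indices(ids)]
        called = g != MISSING
        n_called = called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
        call_rate = n_called / g.shape[1]
        return f, call_rate

    f1, cr1 = _panel(p1)
    f2, cr2 = _panel(p2)
    snp = ~table.sites["is_indel"].to_numpy()
    callable_ = (cr1 >= min_called) & (cr2 >= min_called) & snp
    sp1_alt = (f1 >= min_freq) & (f2 <= 1 - min_freq)
    sp1_ref = (f1 <= 1 - min_freq) & (f2 >= min_freq)
    diagnostic = callable_ & (sp1_alt | sp1_ref)
    idx = np.where(diagnostic)[0]
    sites = pd.DataFrame(
        {
            "chrom": table.sites.loc[idx, "chrom"].to_numpy(),
            "pos": table.sites.loc[idx, "pos"].to_numpy(),
            "site_index": idx,
            # dosage value of the homozygote for each species' allele
            "allele_sp1": np.where(sp1_alt[idx], 2, 0).astype(int),
            "allele_sp2": np.where(sp1_alt[idx], 0, 2).astype(int),
        }
    )
    return DiagnosticIndex(
        sites=sites,
        panel_sizes=(len(p1), len(p2)),
        min_freq=min_freq,
        min_called=min_called,
    )


def classify_and_call_segments(
    table: VariantTable,
    index: DiagnosticIndex,
    sample_id: str,
    donor_species: str,
    layout: GenomeLayout,
    min_span: int = 500,
    min_sites: int = 3,
    het_supports: bool = True,
    boundary: str = "midpoint",
) -> pd.DataFrame:
    """Call introgression segments for one accession.

    ``donor_species`` ("sp1" or "sp2") names the species whose alleles
    count as evidence of introgression into this accession.
    """
    if boundary not in ("midpoint", "sites"):
        raise PipelineError(f"boundary must be 'midpoint' or 'sites', got {boundary!r}")
    if donor_species not in ("sp1", "sp2"):
        raise PipelineError(f"unknown donor species {donor_species!r}")
    col = table.sample_indices([sample_id])[0]
    allele_col = f"allele_{donor_species}"
    rows = []
    submap = layout.subgenome_map()
    for chrom, chunk in index.sites.groupby("chrom", sort=False):
        pos = chunk["pos"].to_numpy()
        site_idx = chunk["site_index"].to_numpy()
        donor_hom = chunk[allele_col].to_numpy()  # dosage of donor homozygote
        g = table.genotypes[site_idx, col].astype(int)
        donor_dosage = np.where(donor_hom == 2, g, 2 - g)
        donor_dosage[g == MISSING] = MISSING
        called = donor_dosage != MISSING
        support = called & (
            (donor_dosage >= 1) if het_supports else (donor_dosage == 2)
        )
        oppose = called & (donor_dosage == 0)

        run: list[int] = []  # indices (into pos) of supporting sites
        last_informative_before: int | None = None  # pos of opposing site before run
        prev_opposing: int | None = None
        for i in range(len(pos)):
            if support[i]:
                if not run:
                    last_informative_before = prev_opposing
                run.append(i)
            elif oppose[i]:
                if run:
                    rows.append(
                        _finish_run(run, pos, int(pos[i]), last_informative_before,
                                    boundary, chrom, sample_id, donor_species, submap)
                    )
                    run = []
                prev_opposing = int(pos[i])
        if run:
            rows.append(
                _finish_run(run, pos, None, last_informative_before,
                            boundary, chrom, sample_id, donor_species, submap)
            )
    segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    keep = (segs["end"] - segs["start"] + 1 >= min_span) & (segs["n_sites"] >= min_sites)
    return segs[keep].reset_index(drop=True)


def _finish_run(run, pos, next_opposing, prev_opposing, boundary,
                chrom, sample_id, donor, submap):
    first, last = int(pos[run[0]]), int(pos[run[-1]])
    if boundary == "midpoint":
        start = (prev_opposing + first + 1) // 2 if prev_opposing is not None else first
        end = (last + next_opposing) // 2 if next_opposing is not None else last
    else:
        start, end = first, last
    return (sample_id, chrom, start, end, len(run), donor, submap.get(chrom, ""))


def call_all_segments(
    table: VariantTable,
    index: DiagnosticIndex,
    sheet: SampleSheet,
    layout: GenomeLayout,
    panel_samples: Sequence[str],
    min_span: int = 500,
    min_sites: int = 3,
    het_supports: bool = True,
    boundary: str = "midpoint",
    max_gap: int = 30_000,
) -> pd.DataFrame:
    """Call + merge segments for every non-panel accession; donor is the
    other species per the sample sheet."""
    panel = set(panel_samples)
    rows = []
    t = sheet.table[~sheet.table["excluded"]]
    for _, rec in t.iterrows():
        s = rec["sample_id"]
        if s in panel or s not in set(table.samples):
            continue
        donor = "sp2" if rec["species"] == "sp1" else "sp1"
        segs = classify_and_call_segments(
            table, index, s, donor, layout,
            min_span=min_span, min_sites=min_sites,
            het_supports=het_supports, boundary=boundary,
        )
        rows.append(merge_segments(segs, max_gap=max_gap))
    if not rows:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def merge_segments(segments: pd.DataFrame, max_gap: int = 30_000) -> pd.DataFrame:
    """Merge consecutive same-sample same-donor segments on one chromosome
    whose gap (next.start - prev.end) is strictly below ``max_gap``.

    A single sorted sweep reaches the fixed point.
    """
    if segments.empty:
        return segments.copy()
    seg = segments.sort_values(["sample_id", "donor", "chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None
    cur_key = None
    for _, r in seg.iterrows():
        key = (r["sample_id"], r["donor"], r["chrom"])
        if cur is not None and key == cur_key and int(r["start"]) - cur["end"] < max_gap:
            cur["end"] = max(cur["end"], int(r["end"]))
            cur["n_sites"] += int(r["n_sites"])
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "sample_id": r["sample_id"], "chrom": r["chrom"],
                "start": int(r["start"]), "end": int(r["end"]),
                "n_sites": int(r["n_sites"]), "donor": r["donor"],
                "subgenome": r["subgenome"],
            }
            cur_key = key
    rows.append(cur)
    out = pd.DataFrame(rows)
    return out[SEGMENT_COLUMNS].sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Summaries


def flag_recent_hybrids(
    segments: pd.DataFrame,
    layout: GenomeLayout,
    max_fraction: float = 0.10,
) -> pd.DataFrame:
    """Flag accessions whose total introgressed bp exceeds ``max_fraction``
    of the genome (recent interspecific hybrids)."""
    genome = layout.total_length
    if segments.empty:
        return pd.DataFrame(columns=["sample_id", "introgressed_bp", "fraction", "flagged"])
    per = (
        segments.assign(length=lambda d: d["end"] - d["start"] + 1)
        .groupby("sample_id")["length"].sum()
        .rename("introgressed_bp")
        .reset_index()
    )
    per["fraction"] = per["introgressed_bp"] / genome
    per["flagged"] = per["fraction"] > max_fraction
    return per


def summarize_introgression(
    segments: pd.DataFrame,
    sheet: SampleSheet,
    layout: GenomeLayout,
    annotation: GeneAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-accession, per-population, and per-gene introgression summaries.

    Returns ``(per_accession, per_population, gene_sharing)``:

    * per accession: region count, total Mb, gene count, split by subgenome;
    * per population class (within each recipient species): means across
      that class's accessions — regions per chromosome, total Mb by
      subgenome, introgressed gene count;
    * per gene: the number of accessions sharing introgression over it.
    """
    t = sheet.table[~sheet.table["excluded"]]
    meta = t.set_index("sample_id")[["species", "population"]]
    submap = layout.subgenome_map()
    n_chroms = {
        "all": len(layout.chroms),
        "A": int((layout.table["subgenome"] == "A").sum()),
        "D": int((layout.table["subgenome"] == "D").sum()),
    }

    gene_lists: list[list[str]] = []
    if annotation is not None and not segments.empty:
        gene_lists = genes_in_intervals(
            list(zip(segments["chrom"], segments["start"], segments["end"])), annotation
        )

    acc_rows = []
    gene_sharing: dict[str, set[str]] = {}
    for sample in meta.index:
        segs = segments[segments["sample_id"] == sample] if not segments.empty else segments
        lengths = (segs["end"] - segs["start"] + 1) if len(segs) else pd.Series(dtype=int)
        sub = segs["chrom"].map(submap) if len(segs) else pd.Series(dtype=str)
        genes: set[str] = set()
        genes_by_sub = {"A": set(), "D": set()}
        if annotation is not None and len(segs):
            for (_, seg), lst in zip(segs.iterrows(), [gene_lists[i] for i in segs.index]):
                genes.update(lst)
                genes_by_sub[submap[seg["chrom"]]].update(lst)
                for gid in lst:
                    gene_sharing.setdefault(gid, set()).add(sample)
        acc_rows.append(
            {
                "sample_id": sample,
                "species": meta.loc[sample, "species"],
                "population": meta.loc[sample, "population"],
                "n_regions": int(len(segs)),
                "n_regions_A": int((sub == "A").sum()),
                "n_regions_D": int((sub == "D").sum()),
                "total_mb": float(lengths.sum() / 1e6),
                "total_mb_A": float(lengths[(sub == "A").to_numpy()].sum() / 1e6) if len(segs) else 0.0,
                "total_mb_D": float(lengths[(sub == "D").to_numpy()].sum() / 1e6) if len(segs) else 0.0,
                "n_genes": len(genes),
                "n_genes_A": len(genes_by_sub["A"]),
                "n_genes_D": len(genes_by_sub["D"]),
            }
        )
    per_accession = pd.DataFrame(acc_rows)

    pop_rows = []
    if not per_accession.empty:
        for (species, population), chunk in per_accession.groupby(["species", "population"]):
            pop_rows.append(_population_row(species, population, chunk, n_chroms))
        for species, chunk in per_accession.groupby("species"):
            pop_rows.append(_population_row(species, "all", chunk, n_chroms))
    per_population = pd.DataFrame(
        pop_rows,
        columns=[
            "species", "population", "n_accessions",
            "mean_regions_per_chrom", "mean_regions_per_chrom_A", "mean_regions_per_chrom_D",
            "mean_total_mb", "mean_total_mb_A", "mean_total_mb_D",
            "mean_n_genes", "mean_n_genes_A", "mean_n_genes_D",
        ],
    )

    sharing = pd.DataFrame(
        sorted((g, len(s)) for g, s in gene_sharing.items()),
        columns=["gene_id", "n_accessions"],
    )
    return per_accession, per_population, sharing


def _population_row(species, population, chunk, n_chroms):
    return (
        species,
        population,
        int(len(chunk)),
        float(chunk["n_regions"].mean() / n_chroms["all"]),
        float(chunk["n_regions_A"].mean() / max(n_chroms["A"], 1)),
        float(chunk["n_regions_D"].mean() / max(n_chroms["D"], 1)),
        float(chunk["total_mb"].mean()),
        float(chunk["total_mb_A"].mean()),
        float(chunk["total_mb_D"].mean()),
        float(chunk["n_genes"].mean()),
        float(chunk["n_genes_A"].mean()),
        float(chunk["n_genes_D"].mean()),
    )
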