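"""End-to-end orchestration: simulate/load -> QC -> diversity -> sweeps ->
introgression, with a manifest.

A run is driven by one :class:`RunConfig` (usually loaded from YAML) that
names either input files (VCF + GFF3 + layout + sample sheet) or a
``simulate`` block.  Stages run in a fixed order, every intermediate is
written under the output directory, and the manifest records parameters,
the seed, per-stage record counts, and a sha256 digest of every file, so
a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import introgression as intro
from . import sweeps as sw
from . import variants as var
from .core import (
    GeneAnnotation,
    GenomeLayout,
    PipelineError,
    SampleSheet,
    VariantTable,
    read_variants,
    write_bed,
    log,
)
from .sim import SimConfig, simulate_cohort, write_cohort


@dataclass
class RunConfig:
    """Parameters of one pipeline run (exactly one of ``inputs`` /
    ``simulate`` must be given)."""

    out_dir: str
    seed: int = 0
    inputs: dict | None = None       # vcf, gff3, layout, samples paths
    simulate: dict | None = None     # SimConfig fields
    window: int = 100_000
    step: int = 20_000
    sweep_q: float = 0.05
    sweep_mode: str = "and"
    flank_bp: int = 5000
    sample_max_missing: float = 0.25
    site_max_missing: float = 0.25
    min_maf: float = 0.05
    intro_min_span: int = 500
    intro_min_sites: int = 3
    intro_max_gap: int = 30_000
    intro_min_freq: float = 0.95
    intro_min_called: float = 0.8
    hybrid_max_fraction: float = 0.10
    overlap_permutations: int = 1000

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise PipelineError("exactly one of 'inputs' and 'simulate' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.data: dict = {
            "config": config.to_dict(),
            "seed": config.seed,
            "stages": {},
            "files": {},
        }

    def record(self, stage: str, counts: dict, files: dict[str, Path]) -> None:
        self.data["stages"][stage] = counts
        for name, path in files.items():
            rel = str(Path(path).relative_to(self.out_dir))
            self.data["files"][f"{stage}/{name}"] = {
                "path": rel,
                "sha256": _sha256(Path(path)),
            }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim_cfg = SimConfig.from_dict(config.simulate) if "chrom_specs" in config.simulate else SimConfig(**config.simulate)
        table, sheet, annotation, layout, truth = simulate_cohort(sim_cfg)
        files = write_cohort(table, sheet, annotation, layout, truth, out / "inputs")
        return table, sheet, annotation, layout, files
    paths = config.inputs
    layout = GenomeLayout.from_tsv(paths["layout"])
    sheet = SampleSheet.from_tsv(paths["samples"])
    table = read_variants(paths["vcf"], layout)
    annotation = GeneAnnotation.from_gff3(paths["gff3"])
    return table, sheet, annotation, layout, {}


def _scan_species(table, sheet, layout, config):
    """Species with usable landrace2 + cultivar panels for the sweep scan."""
    out = []
    for sp in sorted(set(sheet.table["species"])):
        lr2 = sheet.samples(species=sp, population="landrace2")
        cul = sheet.samples(species=sp, population="cultivar")
        lr2 = [s for s in lr2 if s in set(table.samples)]
        cul = [s for s in cul if s in set(table.samples)]
        if len(lr2) >= 2 and len(cul) >= 2:
            out.append((sp, lr2, cul))
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the manifest path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)

    stage = "inputs"
    try:
        table, sheet, annotation, layout, files = _load_inputs(config, out)
        manifest.record(
            stage,
            {"n_sites": table.n_sites, "n_samples": table.n_samples,
             "n_genes": len(annotation.genes)},
            files,
        )

        # ---------------- QC ----------------
        stage = "qc"
        table, sheet = var.filter_samples_by_missing(
            table, sheet, config.sample_max_missing
        )
        table = var.filter_sites(
            table, layout, config.site_max_missing, config.min_maf
        )
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        table.write_vcf(qc_dir / "filtered.vcf", layout)
        sheet.to_tsv(qc_dir / "samples_qc.tsv")
        manifest.record(
            stage,
            {"n_sites": table.n_sites, "n_samples": table.n_samples,
             "n_excluded_samples": int(sheet.table["excluded"].sum()),
             "site_max_missing": config.site_max_missing,
             "min_maf": config.min_maf},
            {"filtered_vcf": qc_dir / "filtered.vcf",
             "samples": qc_dir / "samples_qc.tsv"},
        )
        snp = table.snps()

        # ---------------- diversity ----------------
        stage = "diversity"
        div_dir = out / "diversity"
        div_dir.mkdir(exist_ok=True)
        div_files: dict[str, Path] = {}
        counts: dict = {}
        painted = var.paint_feature_classes(annotation, layout, config.flank_bp)
        feats = var.annotate_site_features(snp, annotation, layout, config.flank_bp, painted)
        lengths = var.feature_class_lengths(painted, layout)
        strat = div.stratified_pi(snp, feats, lengths, sheet)
        strat.to_csv(div_dir / "stratified_pi.tsv", sep="\t", index=False)
        div_files["stratified_pi"] = div_dir / "stratified_pi.tsv"

        window_tables = {}
        for sp, lr2, cul in _scan_species(snp, sheet, layout, config):
            wstats = div.window_stats(snp, lr2, cul, layout, config.window, config.step)
            path = div_dir / f"windows_{sp}.tsv"
            wstats.to_csv(path, sep="\t", index=False, float_format="%.8g")
            window_tables[sp] = wstats
            div_files[f"windows_{sp}"] = path
            counts[f"windows_{sp}"] = len(wstats)

        for sp in sorted(set(sheet.table["species"])):
            ids = [s for s in sheet.samples(species=sp) if s in set(snp.samples)]
            if len(ids) >= 3:
                coords, frac = div.pca_patterson(snp, ids)
                coords.insert(0, "sample_id", coords.index)
                path = div_dir / f"pca_{sp}.tsv"
                coords.to_csv(path, sep="\t", index=False, float_format="%.8g")
                div_files[f"pca_{sp}"] = path
                counts[f"pca_{sp}_pc1_fraction"] = float(frac[0])

        species = sorted(set(sheet.table["species"]))
        if len(species) == 2:
            g1 = [s for s in sheet.samples(species=species[0]) if s in set(snp.samples)]
            g2 = [s for s in sheet.samples(species=species[1]) if s in set(snp.samples)]
            comp = div.wc_fst_components(snp, g1, g2)
            counts["weighted_fst_between_species"] = div.weighted_fst(comp)
        manifest.record(stage, counts, div_files)

        # ---------------- sweeps ----------------
        stage = "sweeps"
        sweep_dir = out / "sweeps"
        sweep_dir.mkdir(exist_ok=True)
        sweep_files: dict[str, Path] = {}
        counts = {}
        regions_by_species = {}
        for sp, wstats in window_tables.items():
            selected, thresholds = sw.joint_top_quantile_scan(
                wstats, config.sweep_q, config.sweep_mode
            )
            regions = sw.merge_selected_windows(selected, layout)
            gene_lists = var.genes_in_intervals(
                list(zip(regions["chrom"], regions["start"], regions["end"])), annotation
            )
            regions["n_genes"] = [len(g) for g in gene_lists]
            regions_by_species[sp] = regions
            tsv = sweep_dir / f"sweep_regions_{sp}.tsv"
            regions.to_csv(tsv, sep="\t", index=False, float_format="%.8g")
            bed = sweep_dir / f"sweep_regions_{sp}.bed"
            write_bed(regions, bed) if len(regions) else bed.write_text("")
            summary = sw.subgenome_summary(regions, layout, annotation)
            spath = sweep_dir / f"sweep_subgenomes_{sp}.tsv"
            summary.to_csv(spath, sep="\t", index=False, float_format="%.8g")
            sweep_files.update(
                {f"regions_{sp}": tsv, f"regions_bed_{sp}": bed, f"subgenomes_{sp}": spath}
            )
            counts[f"n_selected_windows_{sp}"] = len(selected)
            counts[f"n_regions_{sp}"] = len(regions)
            counts[f"thresholds_{sp}"] = thresholds
        if len(regions_by_species) == 2:
            (sp_a, ra), (sp_b, rb) = sorted(regions_by_species.items())
            if len(ra) and len(rb):
                result = sw.overlap_permutation_test(
                    ra, rb, layout, config.overlap_permutations, config.seed
                )
                jpath = sweep_dir / "overlap_test.json"
                result.to_json(jpath)
                sweep_files["overlap_test"] = jpath
                counts["overlap_observed_bp"] = result.observed_overlap_bp
                counts["overlap_p_value"] = result.p_value
        manifest.record(stage, counts, sweep_files)

        # ---------------- introgression ----------------
        stage = "introgression"
        intro_dir = out / "introgression"
        intro_dir.mkdir(exist_ok=True)
        intro_files: dict[str, Path] = {}
        counts = {}
        panel1 = [s for s in sheet.samples(species="sp1", population="wild") if s in set(snp.samples)]
        panel2 = [s for s in sheet.samples(species="sp2", population="wild") if s in set(snp.samples)]
        if len(panel1) >= 2 and len(panel2) >= 2:
            index = intro.build_diagnostic_index(
                snp, panel1, panel2, config.intro_min_freq, config.intro_min_called
            )
            counts["n_diagnostic_sites"] = index.n_sites
            segments = intro.call_all_segments(
                snp, index, sheet, layout, panel1 + panel2,
                min_span=config.intro_min_span, min_sites=config.intro_min_sites,
                max_gap=config.intro_max_gap,
            )
            flags = intro.flag_recent_hybrids(segments, layout, config.hybrid_max_fraction)
            hybrids = set(flags.loc[flags["flagged"], "sample_id"])
            if hybrids:
                sheet = sheet.exclude(sorted(hybrids), "recent hybrid: excess introgression")
                segments = segments[~segments["sample_id"].isin(hybrids)].reset_index(drop=True)
            per_acc, per_pop, sharing = intro.summarize_introgression(
                segments, sheet, layout, annotation
            )
            seg_path = intro_dir / "segments.tsv"
            segments.to_csv(seg_path, sep="\t", index=False)
            bed_path = intro_dir / "segments.bed"
            if len(segments):
                write_bed(segments, bed_path, extra_cols=["sample_id", "donor"])
            else:
                bed_path.write_text("")
            flags_path = intro_dir / "hybrid_flags.tsv"
            flags.to_csv(flags_path, sep="\t", index=False)
            acc_path = intro_dir / "per_accession.tsv"
            per_acc.to_csv(acc_path, sep="\t", index=False, float_format="%.8g")
            pop_path = intro_dir / "per_population.tsv"
            per_pop.to_csv(pop_path, sep="\t", index=False, float_format="%.8g")
            share_path = intro_dir / "gene_sharing.tsv"
            sharing.to_csv(share_path, sep="\t", index=False)
            intro_files = {
                "segments": seg_path, "segments_bed": bed_path,
                "hybrid_flags": flags_path, "per_accession": acc_path,
                "per_population": pop_path, "gene_sharing": share_path,
            }
            counts["n_segments"] = len(segments)
            counts["n_recent_hybrids"] = len(hybrids)
        else:
            log.info("introgression stage skipped: wild panels unavailable")
            counts["skipped"] = "wild panels unavailable"
        manifest.record(stage, counts, intro_files)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return manifest.write()
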