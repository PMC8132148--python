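"""Synthetic allotetraploid two-species cohorts with known truth.

The generator emulates the structure of a resequencing panel of two
diverged cotton species, each sampled as wild / landrace1 / landrace2 /
cultivar populations over an A+D subgenome genome (A chromosomes ~2x the
D length):

* segregating sites are placed uniformly at a configured density; each
  non-diagnostic site draws an ancestral frequency p from a symmetric
  Beta, then a per-population frequency from the Balding-Nichols
  distribution Beta(p(1-F)/F, (1-p)(1-F)/F) with that population's drift
  parameter F.  Setting F(cultivar) >> F(landrace) creates the
  domestication bottleneck: expected heterozygosity scales as (1-F);
* a fraction ``species_divergence`` of sites are species-diagnostic:
  fixed for the reference allele in species 1 and the alternate allele in
  species 2 (outside introgression tracts);
* planted sweeps shrink cultivar allele frequencies toward the nearer
  fixation point so expected heterozygosity in the region scales by the
  configured factor;
* planted introgression tracts overwrite the carrier's genotypes at
  diagnostic sites with donor-species genotypes;
* gene models use a fixed 5'UTR-CDS-intron-CDS-3'UTR template stamped at
  a configured density, with stop-free CDS codons written into the
  generated genome sequence so codon-degeneracy classification works;
* small indels (1-9 bp, geometric lengths) are added for the indel
  classifier.

Genotypes are unphased diploid dosages at homoeolog-resolved positions
(the two subgenomes are carried as separate chromosomes).  Identical
configs (including the seed) produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    POPULATIONS,
    SPECIES,
    GeneAnnotation,
    Gene,
    GenomeLayout,
    PipelineError,
    SampleSheet,
    VariantTable,
    write_bed,
    read_bed,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

# fixed gene template (1500 bp), coordinates relative to gene start
_TPL_LEN = 1500
_TPL_CDS = ((200, 499), (1000, 1299))
_TPL_EXONS = ((0, 499), (1000, 1499))
_TPL_UTR_LEFT = (0, 199)
_TPL_UTR_RIGHT = (1300, 1499)


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``drift_f`` maps population class to the Balding-Nichols F; the
    default makes cultivar heterozygosity one third of landrace2
    heterozygosity ((1-F_c)/(1-F_l2) = 1/3), the magnitude of the
    domestication bottleneck seen in upland cotton.
    """

    chrom_specs: list[tuple[str, int, str]] = field(
        default_factory=lambda: [("ChrA01", 2_000_000, "A"), ("ChrD01", 1_000_000, "D")]
    )
    n_samples: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (sp, pop): n
            for sp in SPECIES
            for pop, n in zip(POPULATIONS, (10, 10, 15, 15))
        }
    )
    snp_density: float = 0.002
    indel_density: float = 0.0
    species_divergence: float = 0.05
    drift_f: dict[str, float] = field(
        default_factory=lambda: {
            "wild": 0.02,
            "landrace1": 0.05,
            "landrace2": 0.05,
            "cultivar": 1.0 - 0.95 / 3.0,  # cultivar het = landrace2 het / 3
        }
    )
    sweeps: list[tuple[str, int, int, float]] = field(default_factory=list)
    tracts: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    gene_density: float = 28.0  # genes per Mb
    missing_rate: float = 0.0
    beta_shape: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        chroms = {name: length for name, length, _ in self.chrom_specs}
        for name, length, sub in self.chrom_specs:
            if length <= 0:
                raise PipelineError(f"chromosome {name}: length must be > 0")
            if sub not in ("A", "D"):
                raise PipelineError(f"chromosome {name}: subgenome must be A or D")
        for chrom, start, end, scale in self.sweeps:
            if chrom not in chroms:
                raise PipelineError(f"sweep on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= chroms[chrom]):
                raise PipelineError(f"sweep {chrom}:{start}-{end} outside bounds")
            if not 0 < scale <= 1:
                raise PipelineError(f"sweep diversity scale {scale} not in (0, 1]")
        by_sample: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for sample, chrom, start, end, donor in self.tracts:
            if chrom not in chroms:
                raise PipelineError(f"tract on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= chroms[chrom]):
                raise PipelineError(f"tract {chrom}:{start}-{end} outside bounds")
            if donor not in SPECIES:
                raise PipelineError(f"unknown donor species {donor!r}")
            by_sample.setdefault((sample, chrom), []).append((start, end))
        for (sample, chrom), ivals in by_sample.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise PipelineError(
                        f"overlapping tracts for sample {sample} on {chrom}"
                    )
        for pop, f in self.drift_f.items():
            if not 0 <= f < 1:
                raise PipelineError(f"drift_f[{pop}]={f} not in [0, 1)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_specs"] = [list(x) for x in self.chrom_specs]
        d["n_samples"] = {f"{sp}:{pop}": n for (sp, pop), n in self.n_samples.items()}
        d["sweeps"] = [list(x) for x in self.sweeps]
        d["tracts"] = [list(x) for x in self.tracts]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["chrom_specs"] = [tuple(x) for x in d["chrom_specs"]]
        d["n_samples"] = {
            tuple(k.split(":")): int(v) for k, v in d["n_samples"].items()
        }
        d["sweeps"] = [tuple(x) for x in d["sweeps"]]
        d["tracts"] = [tuple(x) for x in d["tracts"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort: the planted sweeps and tracts,
    and the realized per-population allele-frequency arrays."""

    config: SimConfig
    sweeps: pd.DataFrame  # chrom, start, end, diversity_scale
    tracts: pd.DataFrame  # sample_id, chrom, start, end, donor
    frequencies: pd.DataFrame  # chrom, pos, is_diagnostic, <species_pop columns>
    seed: int

    def __eq__(self, other: object) -> bool:  # reload-identical contract
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (
            self.config.to_dict() == other.config.to_dict()
            and self.seed == other.seed
            and self.sweeps.equals(other.sweeps)
            and self.tracts.equals(other.tracts)
            and self.frequencies.equals(other.frequencies)
        )


def sample_ids_for(config: SimConfig) -> dict[tuple[str, str], list[str]]:
    """Deterministic sample naming: sp_pop_NNN in species/population order."""
    out = {}
    for sp in SPECIES:
        for pop in POPULATIONS:
            k = config.n_samples.get((sp, pop), 0)
            out[(sp, pop)] = [f"{sp}_{pop}_{i:03d}" for i in range(k)]
    return out


def _shrink_toward_fixation(q: np.ndarray, scale: float) -> np.ndarray:
    """q' with q'(1-q') = scale * q(1-q), taking the root on q's side of
    1/2 so frequencies move toward the nearer fixation point."""
    disc = np.sqrt(np.maximum(0.0, 1.0 - 4.0 * scale * q * (1.0 - q)))
    low = (1.0 - disc) / 2.0
    high = (1.0 + disc) / 2.0
    return np.where(q <= 0.5, low, high)


def _make_annotation(config: SimConfig) -> GeneAnnotation:
    genes = []
    for chrom, length, _sub in config.chrom_specs:
        if config.gene_density <= 0:
            continue
        spacing = int(round(1e6 / config.gene_density))
        start = spacing // 2
        k = 0
        while start + _TPL_LEN - 1 <= length:
            strand = "+" if k % 2 == 0 else "-"
            gid = f"{chrom}.g{k + 1:04d}"
            exons = tuple((start + s, start + e) for s, e in _TPL_EXONS)
            cds = tuple((start + s, start + e) for s, e in _TPL_CDS)
            left = (start + _TPL_UTR_LEFT[0], start + _TPL_UTR_LEFT[1])
            right = (start + _TPL_UTR_RIGHT[0], start + _TPL_UTR_RIGHT[1])
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            genes.append(
                Gene(gid, chrom, strand, start, start + _TPL_LEN - 1,
                     exons, cds, (utr5,), (utr3,))
            )
            start += spacing
            k += 1
    return GeneAnnotation(genes)


def _make_sequences(
    config: SimConfig, annotation: GeneAnnotation, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """uint8 base-code arrays (0..3 = ACGT) with stop-free CDS codons."""
    seqs = {}
    by_chrom = annotation.by_chrom()
    for chrom, length, _sub in config.chrom_specs:
        arr = rng.integers(0, 4, size=length, dtype=np.int8).astype(np.uint8)
        for g in by_chrom.get(chrom, []):
            n_codons = sum(e - s + 1 for s, e in g.cds) // 3
            idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
            cds_str = "".join(_SENSE_CODONS[i] for i in idx)
            codes = np.frombuffer(cds_str.encode(), dtype=np.uint8)
            codes = np.searchsorted(_BASES, codes)  # ACGT are sorted bytes
            positions = []
            for s, e in g.cds:
                positions.extend(range(s, e + 1))
            positions = np.array(positions)
            if g.strand == "-":
                arr[positions[::-1] - 1] = 3 - codes  # complement, reversed
            else:
                arr[positions - 1] = codes
        seqs[chrom] = arr
    return seqs


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def simulate_cohort(
    config: SimConfig,
) -> tuple[VariantTable, SampleSheet, GeneAnnotation, GenomeLayout, SimTruth]:
    """Generate a cohort; same config (incl. seed) gives identical output."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    layout = GenomeLayout.from_specs(config.chrom_specs)
    annotation = _make_annotation(config)
    seqs = _make_sequences(config, annotation, rng)

    ids = sample_ids_for(config)
    ordered_pops = [(sp, pop) for sp in SPECIES for pop in POPULATIONS if ids[(sp, pop)]]
    samples = [s for key in ordered_pops for s in ids[key]]
    sample_col = {s: i for i, s in enumerate(samples)}
    for sample, *_ in config.tracts:
        if sample not in sample_col:
            raise PipelineError(f"tract for unknown sample {sample!r}")

    site_frames = []
    geno_blocks = []
    freq_frames = []
    for chrom, length, _sub in config.chrom_specs:
        seq = seqs[chrom]
        n_exp = config.snp_density * length
        n_raw = rng.poisson(n_exp) if n_exp > 0 else 0
        pos = np.unique(rng.integers(1, length + 1, size=n_raw)) if n_raw else np.array([], dtype=int)
        n = len(pos)
        diag = rng.random(n) < config.species_divergence

        # ancestral frequencies and per-population Balding-Nichols draws
        p_anc = rng.beta(config.beta_shape, config.beta_shape, size=n) if n else np.zeros(0)
        p_anc = np.clip(p_anc, 1e-9, 1 - 1e-9)
        pop_freqs: dict[tuple[str, str], np.ndarray] = {}
        for sp, pop in ordered_pops:
            f = config.drift_f.get(pop, 0.0)
            if f > 0 and n:
                q = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
            else:
                q = p_anc.copy()
            pop_freqs[(sp, pop)] = q

        # sweeps: shrink cultivar frequencies toward fixation inside regions
        for s_chrom, s_start, s_end, scale in config.sweeps:
            if s_chrom != chrom:
                continue
            in_region = (pos >= s_start) & (pos <= s_end)
            for sp in SPECIES:
                key = (sp, "cultivar")
                if key in pop_freqs:
                    q = pop_freqs[key]
                    q[in_region] = _shrink_toward_fixation(q[in_region], scale)

        # diagnostic sites: fixed 0 in sp1, fixed 2 in sp2
        for (sp, pop), q in pop_freqs.items():
            q[diag] = 0.0 if sp == "sp1" else 1.0

        # genotypes
        geno = np.empty((n, len(samples)), dtype=np.int8)
        for sp, pop in ordered_pops:
            cols = [sample_col[s] for s in ids[(sp, pop)]]
            q = pop_freqs[(sp, pop)]
            geno[:, cols] = rng.binomial(
                2, q[:, None], size=(n, len(cols))
            ).astype(np.int8)

        # introgression tracts overwrite diagnostic-site genotypes
        for sample, t_chrom, t_start, t_end, donor in config.tracts:
            if t_chrom != chrom:
                continue
            rows = diag & (pos >= t_start) & (pos <= t_end)
            geno[rows, sample_col[sample]] = 2 if donor == "sp2" else 0

        # SNP alleles: ref from the genome, alt a different base
        ref_codes = seq[pos - 1] if n else np.array([], dtype=np.uint8)
        alt_codes = (ref_codes + rng.integers(1, 4, size=n)) % 4 if n else ref_codes
        snp_sites = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": [_decode(np.array([c])) for c in ref_codes],
                "alt": [_decode(np.array([c])) for c in alt_codes],
                "is_indel": False,
                "indel_length": 0,
            }
        )

        # small indels (for the classifier; no population structure)
        n_ind = rng.poisson(config.indel_density * length) if config.indel_density > 0 else 0
        if n_ind:
            taken = set(pos.tolist())
            ipos = np.unique(rng.integers(1, max(2, length - 12), size=n_ind))
            ipos = np.array([p for p in ipos if p not in taken], dtype=int)
            ilen = np.minimum(rng.geometric(0.5, size=len(ipos)), 9)
            is_ins = rng.random(len(ipos)) < 0.5
            ifreq = rng.uniform(0.05, 0.5, size=len(ipos))
            irows = []
            for p, L_i, ins in zip(ipos, ilen, is_ins):
                anchor = _decode(seq[p - 1 : p])
                if ins:
                    extra = _decode(rng.integers(0, 4, size=int(L_i)).astype(np.uint8))
                    irows.append((chrom, int(p), anchor, anchor + extra, True, int(L_i)))
                else:
                    ref = _decode(seq[p - 1 : p + int(L_i)])
                    irows.append((chrom, int(p), ref, anchor, True, -int(L_i)))
            ind_sites = pd.DataFrame(
                irows, columns=["chrom", "pos", "ref", "alt", "is_indel", "indel_length"]
            )
            ind_geno = rng.binomial(2, ifreq[:, None], size=(len(ipos), len(samples))).astype(np.int8)
            chrom_sites = pd.concat([snp_sites, ind_sites], ignore_index=True)
            chrom_geno = np.vstack([geno, ind_geno]) if n else ind_geno
            order = np.argsort(chrom_sites["pos"].to_numpy(), kind="stable")
            chrom_sites = chrom_sites.iloc[order].reset_index(drop=True)
            chrom_geno = chrom_geno[order]
        else:
            chrom_sites, chrom_geno = snp_sites, geno

        site_frames.append(chrom_sites)
        geno_blocks.append(chrom_geno)
        freq = pd.DataFrame({"chrom": chrom, "pos": pos, "is_diagnostic": diag})
        for (sp, pop), q in pop_freqs.items():
            freq[f"{sp}_{pop}"] = q
        freq_frames.append(freq)

    sites = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "is_indel", "indel_length"])
    )
    geno = (
        np.vstack(geno_blocks) if geno_blocks else np.zeros((0, len(samples)), dtype=np.int8)
    )

    if config.missing_rate > 0 and len(sites):
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = -1

    table = VariantTable(sites, geno, samples)
    sheet = SampleSheet(
        pd.DataFrame(
            [
                (s, sp, pop)
                for sp, pop in ordered_pops
                for s in ids[(sp, pop)]
            ],
            columns=["sample_id", "species", "population"],
        )
    )
    truth = SimTruth(
        config=config,
        sweeps=pd.DataFrame(
            config.sweeps, columns=["chrom", "start", "end", "diversity_scale"]
        ).astype({"chrom": str, "start": int, "end": int, "diversity_scale": float}),
        tracts=pd.DataFrame(
            config.tracts, columns=["sample_id", "chrom", "start", "end", "donor"]
        ).astype({"sample_id": str, "chrom": str, "start": int, "end": int, "donor": str})
        .sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True),
        frequencies=(
            pd.concat(freq_frames, ignore_index=True)
            if freq_frames
            else pd.DataFrame(columns=["chrom", "pos", "is_diagnostic"])
        ),
        seed=config.seed,
    )
    table._sequences = seqs  # cached for optional FASTA output
    return table, sheet, annotation, layout, truth


def sequences_as_strings(table: VariantTable) -> dict[str, str]:
    """Genome sequences attached by :func:`simulate_cohort`."""
    return {k: _decode(v) for k, v in getattr(table, "_sequences", {}).items()}


# ---------------------------------------------------------------------------
# Truth serialization


def write_truth(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """BED truth files + JSON config + TSV frequency arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sweeps": out / "truth_sweeps.bed",
        "tracts": out / "truth_tracts.bed",
        "config": out / "sim_config.json",
        "frequencies": out / "truth_frequencies.tsv",
    }
    write_bed(truth.sweeps, paths["sweeps"], extra_cols=["diversity_scale"])
    tracts = truth.tracts.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
    write_bed(tracts, paths["tracts"], extra_cols=["sample_id", "donor"])
    paths["config"].write_text(
        json.dumps({"config": truth.config.to_dict(), "seed": truth.seed}, indent=2)
        + "\n"
    )
    truth.frequencies.to_csv(
        paths["frequencies"], sep="\t", index=False, float_format="%.17g"
    )
    return paths


def read_truth(out_dir: str | Path) -> SimTruth:
    out = Path(out_dir)
    meta = json.loads((out / "sim_config.json").read_text())
    config = SimConfig.from_dict(meta["config"])
    sweeps = read_bed(out / "truth_sweeps.bed", extra_cols=["diversity_scale"])
    sweeps = sweeps[["chrom", "start", "end", "diversity_scale"]]
    tracts = read_bed(out / "truth_tracts.bed", extra_cols=["sample_id", "donor"])
    tracts = tracts[["sample_id", "chrom", "start", "end", "donor"]].astype(
        {"sample_id": str, "chrom": str, "donor": str}
    )
    freqs = pd.read_csv(
        out / "truth_frequencies.tsv", sep="\t", dtype={"chrom": str},
        float_precision="round_trip",
    )
    if freqs.empty:  # header-only file: restore column dtypes
        casts = {}
        for col in freqs.columns:
            if col == "chrom":
                casts[col] = str
            elif col == "pos":
                casts[col] = int
            elif col == "is_diagnostic":
                casts[col] = bool
            else:
                casts[col] = float
        freqs = freqs.astype(casts)
    return SimTruth(
        config=config,
        sweeps=sweeps.astype({"start": int, "end": int, "diversity_scale": float}),
        tracts=tracts.astype({"start": int, "end": int}),
        frequencies=freqs,
        seed=int(meta["seed"]),
    )


def write_cohort(
    table: VariantTable,
    sheet: SampleSheet,
    annotation: GeneAnnotation,
    layout: GenomeLayout,
    truth: SimTruth,
    out_dir: str | Path,
    fasta: bool = True,
) -> dict[str, Path]:
    """Write the standard-format cohort inputs plus truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "gff3": out / "annotation.gff3",
        "layout": out / "genome_layout.tsv",
        "samples": out / "samples.tsv",
    }
    table.write_vcf(paths["vcf"], layout)
    annotation.to_gff3(paths["gff3"])
    layout.to_tsv(paths["layout"])
    sheet.to_tsv(paths["samples"])
    if fasta and getattr(table, "_sequences", None):
        paths["fasta"] = out / "genome.fa"
        write_fasta(sequences_as_strings(table), paths["fasta"])
    paths.update(write_truth(truth, out))
    return paths


# ---------------------------------------------------------------------------
# Analytic expectations used for calibration


def expected_heterozygosity(beta_shape: float, drift_f: float) -> float:
    """Closed-form E[2 q (1-q)] for the ancestral-Beta + Balding-Nichols
    hierarchy: (1 - F) * 2 * E[p(1-p)] with p ~ Beta(a, a)."""
    a = beta_shape
    e_p1p = a * a / ((2 * a) * (2 * a + 1))  # E[p]E[...]: Beta(a,a) moment
    return (1.0 - drift_f) * 2.0 * e_p1p


def expected_pi(config: SimConfig, population: str) -> float:
    """Expected per-bp diversity of one population class, counting
    diagnostic (within-species monomorphic) sites as invariant."""
    h = expected_heterozygosity(config.beta_shape, config.drift_f.get(population, 0.0))
    return config.snp_density * (1.0 - config.species_divergence) * h
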