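"""Canonical synthetic study designs.

Each function returns the :class:`~cottonpop.sim.SimConfig` for one of the
package's reference experiments.  These are the study conditions used by
the analysis scripts and the acceptance checks; the scale is chosen so a
full run fits a single CPU in minutes while each statistic retains enough
sites for its expectation to be measurable:

* A:D chromosome lengths are 2:1, mirroring the allotetraploid genome;
* SNP density 0.002/bp (so a 100-kb window holds ~200 sites);
* the cultivar drift parameter is set so expected cultivar heterozygosity
  is one third of landrace2 heterozygosity — the magnitude of the upland
  cotton domestication bottleneck (overall pi 0.0008 in cultivars vs
  0.0023 in landrace2).
"""

from __future__ import annotations

from .sim import SimConfig

#: drift giving cultivar het = landrace2 het / 3 given F(landrace2) = 0.05
BOTTLENECK_DRIFT = {
    "wild": 0.02,
    "landrace1": 0.05,
    "landrace2": 0.05,
    "cultivar": 1.0 - 0.95 / 3.0,
}


def bottleneck_study(seed: int) -> SimConfig:
    """Two-species cohort for diversity / Fst / PCA / bottleneck analysis:
    3 Mb genome (A 2 Mb + D 1 Mb), 120 accessions."""
    return SimConfig(
        chrom_specs=[("ChrA01", 2_000_000, "A"), ("ChrD01", 1_000_000, "D")],
        n_samples={
            (sp, pop): n
            for sp in ("sp1", "sp2")
            for pop, n in zip(
                ("wild", "landrace1", "landrace2", "cultivar"), (12, 12, 18, 18)
            )
        },
        snp_density=0.002,
        species_divergence=0.05,
        drift_f=dict(BOTTLENECK_DRIFT),
        gene_density=28.0,
        indel_density=0.0002,
        seed=seed,
    )


# five 200-kb sweeps, cultivar heterozygosity scaled to 0.2
SWEEP_REGIONS = [
    ("ChrA01", 2_000_001, 2_200_000, 0.2),
    ("ChrA01", 6_500_001, 6_700_000, 0.2),
    ("ChrA01", 11_000_001, 11_200_000, 0.2),
    ("ChrD01", 1_500_001, 1_700_000, 0.2),
    ("ChrD01", 4_800_001, 5_000_000, 0.2),
]


def sweep_study(seed: int) -> SimConfig:
    """Sweep-recovery experiment: 20 Mb genome (A 13.4 Mb + D 6.6 Mb),
    200 accessions of one species, five planted 200-kb sweeps."""
    return SimConfig(
        chrom_specs=[("ChrA01", 13_400_000, "A"), ("ChrD01", 6_600_000, "D")],
        n_samples={
            ("sp1", "wild"): 30,
            ("sp1", "landrace1"): 30,
            ("sp1", "landrace2"): 70,
            ("sp1", "cultivar"): 70,
        },
        snp_density=0.002,
        species_divergence=0.0,
        drift_f=dict(BOTTLENECK_DRIFT),
        sweeps=list(SWEEP_REGIONS),
        gene_density=28.0,
        seed=seed,
    )


def introgression_tracts() -> list[tuple[str, str, int, int, str]]:
    """Eight 100-kb donor tracts across six cultivar accessions."""
    return [
        ("sp1_cultivar_000", "ChrA01", 500_001, 600_000, "sp2"),
        ("sp1_cultivar_000", "ChrD01", 1_200_001, 1_300_000, "sp2"),
        ("sp1_cultivar_001", "ChrA01", 2_400_001, 2_500_000, "sp2"),
        ("sp1_cultivar_002", "ChrA01", 4_000_001, 4_100_000, "sp2"),
        ("sp1_cultivar_002", "ChrD01", 2_000_001, 2_100_000, "sp2"),
        ("sp1_cultivar_003", "ChrD01", 500_001, 600_000, "sp2"),
        ("sp1_cultivar_004", "ChrA01", 5_500_001, 5_600_000, "sp2"),
        ("sp1_cultivar_005", "ChrD01", 2_800_001, 2_900_000, "sp2"),
    ]


def introgression_study(seed: int, tracts: list | None = None) -> SimConfig:
    """Tract-recovery experiment: 10 Mb genome, diagnostic-site density
    1 per 5 kb (site density 0.002 x divergence 0.1), wild panels of 12
    per species, tracts planted in cultivar accessions."""
    if tracts is None:
        tracts = introgression_tracts()
    return SimConfig(
        chrom_specs=[("ChrA01", 6_600_000, "A"), ("ChrD01", 3_400_000, "D")],
        n_samples={
            ("sp1", "wild"): 12,
            ("sp1", "cultivar"): 12,
            ("sp2", "wild"): 12,
        },
        snp_density=0.002,
        species_divergence=0.1,
        drift_f={"wild": 0.02, "cultivar": 0.3},
        tracts=list(tracts),
        gene_density=28.0,
        seed=seed,
    )


def pipeline_demo(seed: int) -> SimConfig:
    """Small end-to-end cohort (1.2 Mb, 64 accessions) for smoke runs."""
    return SimConfig(
        chrom_specs=[("ChrA01", 800_000, "A"), ("ChrD01", 400_000, "D")],
        n_samples={
            (sp, pop): 8
            for sp in ("sp1", "sp2")
            for pop in ("wild", "landrace1", "landrace2", "cultivar")
        },
        snp_density=0.002,
        species_divergence=0.08,
        drift_f=dict(BOTTLENECK_DRIFT),
        sweeps=[("ChrA01", 300_001, 400_000, 0.2)],
        tracts=[
            ("sp1_cultivar_000", "ChrA01", 100_001, 200_000, "sp2"),
            ("sp2_cultivar_001", "ChrD01", 150_001, 250_000, "sp1"),
        ],
        gene_density=28.0,
        indel_density=0.0002,
        seed=seed,
    )
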