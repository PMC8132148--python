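# Methods

This note documents the models, estimators, and design choices behind
`cottonpop`, and what the synthetic validation does and does not establish.

## Cohort model

The package analyzes diploid genotype dosages at homoeolog-resolved
positions of an allotetraploid genome: the A and D subgenomes are carried as
separate chromosomes (A chromosomes roughly twice the D length), and no
within-sample homoeolog mixing is modeled — the genotypes are assumed to
come from a mapping pipeline that already separates homoeologs. Samples
belong to one of two species and to a population class (wild, landrace1,
landrace2, cultivar). All intervals are 1-based inclusive internally; BED
output is 0-based half-open.

## Quality control

Two filters, applied in a fixed order that is part of the contract:

1. **Sample removal** — samples with missing-genotype fraction strictly
   above 25% are dropped (recorded on the sample sheet with the reason).
2. **Site filtering** — sites are kept when the called fraction is ≥ 75%
   and the minor-allele frequency, computed over called alleles only, is
   ≥ 5%; only sites on layout-listed chromosomes are retained.

Applying the filters in the other order can give a different result; only
the documented order is supported.

## Diversity

Per-site heterozygosity uses the unbiased pairwise estimator
ĥ = 2c(n−c)/(n(n−1)) over called alleles. Window π divides Σĥ by the *full*
window length (unlisted sites count as invariant), the convention of the
standard windowed-π VCF tools; an accessible-sites denominator was rejected
for comparability. Windows are 100 kb sliding by 20 kb by default; the final
partial window at a chromosome end is emitted with its true length and
flagged `complete=False`. Stratified π divides by feature-class base counts
derived from the same painted classification used to label sites, so
numerator and denominator can never disagree about class boundaries.
4D-site π divides by the count of fourfold-degenerate positions.

Feature classification is strand-aware with a fixed priority when intervals
overlap: 5′UTR/3′UTR > exon (CDS) > intron > upstream > downstream >
intergenic. The upstream/downstream flank is 5 kb by default; the value is
a convention (annotators differ) and is configurable. An indel lying within
the flank of two genes is assigned by the painted priority, i.e. effectively
to the nearer gene's layer.

## Differentiation

Per-site Weir & Cockerham (1984) two-population components a, b, c are
computed from group sample sizes, allele frequencies, and observed
heterozygote frequencies. Sites with no called genotype in either group, or
with fewer than two individuals overall (n̄ ≤ 1, where the estimator is
undefined), are flagged unusable and excluded from sums. Weighted
F<sub>st</sub> = Σa/Σ(a+b+c) retains negative per-site components — the
ratio-of-sums ("weighted") estimator — and one code path serves per-window
and genome-wide scopes. Monomorphic-in-both sites contribute 0/0 and are
skipped via the usable mask. On Balding–Nichols cohorts with both
populations at drift F, the genome-wide estimate converges to F (verified
within ±0.02 at 10⁵ sites).

## PCA

smartpca-style normalization: per site, center by the mean dosage μ and
scale by √(p̂(1−p̂)) with p̂ = μ/2; missing dosages are mean-imputed (only
here — π and F<sub>st</sub> exclude missing calls per site). Coordinates are
eigenvectors of the sample covariance scaled by the singular values, with a
deterministic sign (the largest-magnitude coordinate of each axis is made
positive). Zero-variance input is an error.

## Sweep scan

The scan contrasts the cultivar panel with the landrace2 panel it derives
from. Both criteria are upper-tail: large π<sub>L2</sub>/π<sub>c</sub>
(diversity lost in cultivars) and large F<sub>st</sub>. The ratio form is
used rather than the difference (a difference mode would order windows
differently; it is deliberately not the default). Windows with undefined
values (π<sub>c</sub> = 0 or no usable F<sub>st</sub> sites) are excluded
from ranking and selection. Thresholds are the (1−q) quantiles over defined
windows and are inclusive (≥), so threshold ties select together and the
result does not depend on row order. The default combines the two criteria
by intersection; union mode is a flag. Selected windows that overlap or
book-end merge into regions whose statistics are means over member windows;
merging is idempotent.

The between-set overlap test re-places one region set N times (default
1000): lengths preserved, starts uniform on the same chromosome (preserving
chromosome assignment controls for the A:D length asymmetry; genome-wide
placement is an option), overlaps among placed regions allowed, observed
and permuted overlaps measured as intersection of the set unions,
p = (1 + #{perm ≥ obs})/(N + 1). Under a random-placement null the test is
calibrated (super-uniform p at the 5% level over 200 replicates) and the
permuted mean matches the L₁L₂/G closed form for single regions.

## Introgression

A genotype-level adaptation of read-based interspecific tract calling: the
original two-threshold structure (evidence depth + physical span) is kept
as ≥ 3 diagnostic SNPs over ≥ 500 bp, since read depth is unavailable at
the VCF level.

* **Diagnostic index** — a site is diagnostic when one allele is at
  frequency ≥ 0.95 among called alleles in species 1's wild panel and the
  other allele ≥ 0.95 in species 2's wild panel, with ≥ 80% call rate in
  both. 0.95 rather than strict fixation tolerates rare panel miscalls; a
  1.0 setting is available.
* **Segment calling** — per accession, a diagnostic genotype carrying ≥ 1
  donor allele is donor-supporting (introgressed material is frequently
  hemizygous after backcrossing in selfing lineages; a strict
  homozygous-donor mode exists). Runs of supporting sites are broken by
  recipient-homozygous diagnostic sites but not by missing genotypes.
* **Boundaries** — segment ends default to the midpoint between the
  bounding supporting site and the adjacent opposing diagnostic site, the
  unbiased estimate of a breakpoint that is uniform between informative
  markers. Restricting the segment to the supporting-site span
  (`boundary="sites"`) biases each end inward by half the local marker gap
  — at 1 marker / 5 kb that costs ~5% of a 100-kb tract per side — so the
  midpoint rule is the default. Either way the breakpoint error is bounded
  by one inter-marker gap.
* **Merging** — segments of the same accession/donor/chromosome merge when
  the gap is strictly below 30 kb; a single sorted sweep reaches the fixed
  point.
* **Recent hybrids** — accessions with > 10% of the genome called
  introgressed are flagged and excluded from population summaries. The 10%
  default leaves an order of magnitude of headroom above the largest
  introgression fraction plausibly retained in a non-hybrid accession
  (observed maxima in comparable panels are ~1.7%); it is configurable.

Summaries report, per accession and averaged per population class: region
counts per chromosome, total introgressed length (Mb) split by subgenome,
and introgressed gene counts (a gene counts when a segment overlaps its
span by ≥ 1 bp), plus per-gene accession-sharing counts.

## Synthetic cohorts

The generator emulates the structure the statistics are designed for:

* **Frequencies** — ancestral p ~ Beta(½, ½) (a U-shaped frequency
  spectrum), then per-population Balding–Nichols draws with drift F per
  population class. Expected heterozygosity is (1−F)·E[2p(1−p)] =
  (1−F)·0.25 in closed form, which calibrates π and F<sub>st</sub> tests.
  The default drift values (wild 0.02, landraces 0.05, cultivar 0.6833)
  put cultivar diversity at exactly one third of landrace2 diversity — the
  magnitude of the domestication bottleneck in upland cotton.
* **Sweeps** — imposed on end-state frequencies: inside a region, cultivar
  frequencies move to the root of q′(1−q′) = s·q(1−q) on their side of ½,
  so expected heterozygosity scales by s exactly. No selection dynamics
  through time are simulated.
* **Diagnostic sites** — a fraction (`species_divergence`) of sites are
  fixed ref in species 1 and fixed alt in species 2; planted tracts
  overwrite the carrier's genotypes at the diagnostic sites they span.
* **Genes** — a fixed 1.5-kb template (5′UTR 200 — CDS 300 — intron 500 —
  CDS 300 — 3′UTR 200) stamped at 28 genes/Mb with alternating strands;
  CDS codons are sampled from the 61 sense codons and written into the
  generated genome sequence, so codon-degeneracy classification is exact.
* **Indels** — lengths 1–9 bp, geometric(½) truncated at 9, random sign,
  no population structure; they exercise the indel classifier only.
* **Determinism** — one `numpy` generator seeded from the config seed in a
  fixed order; identical configs give byte-identical VCF/GFF3/FASTA/BED.

Reference scales (`cottonpop.studies`): diversity cohort 3 Mb / 120
accessions; sweep cohort 20 Mb / 200 accessions with five 200-kb sweeps at
s = 0.2; introgression cohort 10 Mb with divergence 0.1 (1 diagnostic site
per 5 kb) and eight 100-kb tracts. Chromosome lengths keep the 2:1 A:D
asymmetry, and SNP density is 0.002/bp throughout (~200 sites per 100-kb
window).

### What the simulations do not capture

Balding–Nichols sites are exchangeable and unlinked: there is no linkage
disequilibrium, no recombination map, no allele-frequency correlation along
the chromosome, and sweeps/tracts have hard edges. Passing the recovery
tests therefore shows the estimators and callers are correct and calibrated
under the stated model, not that the scan's 5% quantile or the segment
thresholds have any particular sensitivity/specificity on real data, where
background LD and demography can mimic or blur both signals. The scan in
particular detects any process that removes cultivar diversity locally —
demographic history can produce sweep-like patterns, and no demographic
null calibration is attempted. Read-level effects (mapping bias between
subgenomes, calling error) are also outside the model; missing data can be
injected but defaults to zero.

## Numerical choices

* Dosages are int8 with −1 for missing; all estimators mask rather than
  impute (PCA excepted, see above).
* Quantile thresholds use `numpy`'s default linear interpolation; selection
  is ≥-inclusive.
* π-ratio is NaN-flagged when the denominator π is 0; weighted
  F<sub>st</sub> is NaN when the component sum is non-positive.
* Midpoint boundaries use integer division; at a chromosome end with no
  flanking opposing marker the supporting-site position is used unchanged.
* The VCF/GFF3/BED/TSV writers are deterministic plain-text emitters (no
  timestamps or tool-version lines), because byte-identical reruns are part
  of the pipeline contract; reading uses cyvcf2, gffutils, and pyfaidx.
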