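"""Population-genetic statistics.

Nucleotide diversity (pi) is the average number of pairwise nucleotide
differences per site.  From unphased diploid dosages the per-site unbiased
estimator is

    h = 2 c (n - c) / (n (n - 1))

with n called alleles and c alt copies; window pi sums h over the sites in
a window and divides by the *full* window length (unlisted sites count as
invariant), matching the windowed-pi convention of standard VCF toolkits.
Default windows are 100 kb sliding by 20 kb.

Between-group differentiation uses the Weir & Cockerham (1984) two-
population variance components a (among), b (between individuals within),
c (within individuals); the "weighted" Fst over any set of sites is the
ratio of sums  sum(a) / sum(a + b + c).  Negative per-site components are
retained (no clamping).

PCA follows the smartpca convention: per-site centering by mean dosage and
scaling by sqrt(p(1-p)) with p estimated from the mean dosage; missing
dosages are mean-imputed; coordinates come from an eigendecomposition of
the sample covariance with a deterministic sign (the largest-magnitude
coordinate of each axis is positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenomeLayout, PipelineError, SampleSheet, VariantTable


# ---------------------------------------------------------------------------
# Per-site building blocks


def allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, c): called allele count and alt-allele count per site."""
    called = genotypes != MISSING
    n = 2 * called.sum(axis=1)
    c = np.where(called, genotypes, 0).sum(axis=1)
    return n, c


def site_heterozygosity(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise-difference heterozygosity
    h = 2c(n-c)/(n(n-1)); 0 where fewer than 2 called alleles."""
    n, c = allele_counts(genotypes)
    h = np.zeros(len(n), dtype=float)
    ok = n >= 2
    nn = n[ok].astype(float)
    cc = c[ok].astype(float)
    h[ok] = 2.0 * cc * (nn - cc) / (nn * (nn - 1.0))
    return h


# ---------------------------------------------------------------------------
# Windows


def window_spans(chrom_len: int, window: int = 100_000, step: int = 20_000):
    """(start, end, complete) tuples tiling [1, chrom_len]; the final
    partial window keeps its true shorter length and is flagged."""
    if window < step:
        raise PipelineError(f"window ({window}) must be >= step ({step})")
    start = 1
    while start <= chrom_len:
        end = min(start + window - 1, chrom_len)
        yield start, end, end - start + 1 == window
        start += step


def _window_sums(pos: np.ndarray, values: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Sum ``values`` (aligned with sorted ``pos``) over [start, end] spans."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    return csum[hi] - csum[lo], hi - lo


def windowed_pi(
    table: VariantTable,
    sample_ids: Sequence[str],
    layout: GenomeLayout,
    window: int = 100_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one sample subset."""
    if len(sample_ids) < 2:
        raise PipelineError("windowed_pi needs >= 2 samples")
    sub = table.subset_samples(list(sample_ids))
    h = site_heterozygosity(sub.genotypes)
    rows = []
    for chrom in layout.chroms:
        mask = (sub.sites["chrom"] == chrom).to_numpy()
        pos = sub.sites.loc[mask, "pos"].to_numpy()
        hv = h[mask]
        spans = list(window_spans(layout.length(chrom), window, step))
        starts = np.array([s for s, _, _ in spans])
        ends = np.array([e for _, e, _ in spans])
        sums, counts = _window_sums(pos, hv, starts, ends)
        for (s, e, complete), tot, k in zip(spans, sums, counts):
            length = e - s + 1
            rows.append((chrom, s, e, length, complete, int(k), tot / length))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "length", "complete", "n_sites", "pi"],
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) components


@dataclass
class FstComponents:
    """Per-site W&C variance components for one two-group comparison."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    usable: np.ndarray  # sites with data in both groups and nbar > 1

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"a": self.a, "b": self.b, "c": self.c, "usable": self.usable})


def wc_fst_components(
    table: VariantTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> FstComponents:
    """Two-population Weir & Cockerham (1984) a, b, c per site.

    Sites lacking a called genotype in either group (or with a single
    individual overall) are flagged unusable and excluded from sums.
    """
    if set(group_a) & set(group_b):
        raise PipelineError("Fst groups overlap")
    ga = table.genotypes[:, table.sample_indices(list(group_a))]
    gb = table.genotypes[:, table.sample_indices(list(group_b))]

    def _group(g):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)            # individuals
        p = np.where(called, g, 0).sum(axis=1) / np.maximum(2 * n, 1)
        het = ((g == 1) & called).sum(axis=1) / np.maximum(n, 1)
        return n, p, het

    n1, p1, h1 = _group(ga)
    n2, p2, h2 = _group(gb)
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return FstComponents(a=a, b=b, c=c, usable=usable)


def weighted_fst(components: FstComponents, mask: np.ndarray | None = None) -> float:
    """Ratio-of-sums estimator sum(a)/sum(a+b+c) over usable sites in
    ``mask`` scope; NaN when the denominator is not positive."""
    use = components.usable.copy()
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    if not use.any():
        return float("nan")
    num = components.a[use].sum()
    den = (components.a[use] + components.b[use] + components.c[use]).sum()
    if den <= 0:
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# Joint window statistics for the sweep scan


def window_stats(
    table: VariantTable,
    group_numerator: Sequence[str],
    group_denominator: Sequence[str],
    layout: GenomeLayout,
    window: int = 100_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Per-window pi for both groups, pi_ratio (numerator/denominator,
    NaN-flagged where the denominator pi is 0), and windowed weighted Fst.

    For the domestication scan the numerator group is the landrace panel
    and the denominator the cultivar panel, so large pi_ratio marks loss of
    diversity in the cultivars.
    """
    pin = windowed_pi(table, group_numerator, layout, window, step)
    pid = windowed_pi(table, group_denominator, layout, window, step)
    comp = wc_fst_components(table, group_numerator, group_denominator)
    num = np.where(comp.usable, comp.a, 0.0)
    den = np.where(comp.usable, comp.a + comp.b + comp.c, 0.0)
    out = pin.rename(columns={"pi": "pi_num", "n_sites": "n_sites_num"})
    out["pi_den"] = pid["pi"]
    fst = np.full(len(out), np.nan)
    i = 0
    for chrom in layout.chroms:
        mask = (table.sites["chrom"] == chrom).to_numpy()
        pos = table.sites.loc[mask, "pos"].to_numpy()
        spans = out.loc[out["chrom"] == chrom]
        starts = spans["start"].to_numpy()
        ends = spans["end"].to_numpy()
        nsum, _ = _window_sums(pos, num[mask], starts, ends)
        dsum, _ = _window_sums(pos, den[mask], starts, ends)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(dsum > 0, nsum / dsum, np.nan)
        fst[i : i + len(spans)] = f
        i += len(spans)
    out["fst"] = fst
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi_ratio"] = np.where(out["pi_den"] > 0, out["pi_num"] / out["pi_den"], np.nan)
    return out


# ---------------------------------------------------------------------------
# Stratified diversity


def stratified_pi(
    table: VariantTable,
    site_features: pd.DataFrame,
    class_lengths: pd.DataFrame,
    sheet: SampleSheet,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """pi per (group x feature_class x subgenome), denominated by the
    feature-class base counts.

    ``groups`` defaults to every (species, population) stratum present in
    the sample sheet plus an "all" stratum per species.  A stratum of zero
    length is flagged with NaN rather than divided.
    """
    if groups is None:
        groups = {}
        t = sheet.table[~sheet.table["excluded"]]
        for (sp, pop), grp in t.groupby(["species", "population"]):
            groups[f"{sp}/{pop}"] = list(grp["sample_id"])
        for sp, grp in t.groupby("species"):
            groups[f"{sp}/all"] = list(grp["sample_id"])
    lengths = (
        class_lengths.groupby(["subgenome", "feature_class"])["length_bp"].sum()
    )
    total_lengths = class_lengths.groupby("feature_class")["length_bp"].sum()
    rows = []
    for name, ids in groups.items():
        ids = [s for s in ids if s in set(table.samples)]
        if len(ids) < 2:
            continue
        h = site_heterozygosity(table.subset_samples(ids).genotypes)
        frame = pd.DataFrame(
            {
                "feature_class": site_features["feature_class"].to_numpy(),
                "subgenome": site_features["subgenome"].to_numpy(),
                "h": h,
            }
        )
        by = frame.groupby(["subgenome", "feature_class"])["h"].agg(["sum", "size"])
        for (sub, cls), (hsum, k) in by.iterrows():
            L = int(lengths.get((sub, cls), 0))
            rows.append((name, cls, sub, int(k), L, hsum / L if L > 0 else np.nan))
        byc = frame.groupby("feature_class")["h"].agg(["sum", "size"])
        for cls, (hsum, k) in byc.iterrows():
            L = int(total_lengths.get(cls, 0))
            rows.append((name, cls, "all", int(k), L, hsum / L if L > 0 else np.nan))
        rows.append(
            (name, "overall", "all", int(len(h)),
             int(class_lengths["length_bp"].sum()),
             h.sum() / class_lengths["length_bp"].sum())
        )
    return pd.DataFrame(
        rows,
        columns=["group", "feature_class", "subgenome", "n_sites", "length_bp", "pi"],
    )


def fourfold_pi(
    table: VariantTable,
    fourfold_sites: set[tuple[str, int]],
    sample_ids: Sequence[str],
) -> float:
    """pi over fourfold-degenerate positions: summed h at 4D SNPs divided
    by the number of 4D positions in the genome."""
    if not fourfold_sites:
        return float("nan")
    keys = list(zip(table.sites["chrom"], table.sites["pos"].astype(int)))
    mask = np.array([k in fourfold_sites for k in keys])
    h = site_heterozygosity(table.subset_samples(list(sample_ids)).genotypes)
    return float(h[mask].sum() / len(fourfold_sites))


# ---------------------------------------------------------------------------
# PCA (Patterson normalization)


def pca_patterson(
    table: VariantTable, sample_ids: Sequence[str], n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the genotype matrix.

    Returns (coordinates frame indexed by sample, explained-variance
    fractions).  Sites that are monomorphic after imputation are dropped.
    """
    if len(sample_ids) < 3:
        raise PipelineError("PCA needs >= 3 samples")
    sub = table.subset_samples(list(sample_ids))
    g = sub.genotypes.astype(float).T  # samples x sites
    miss = g == MISSING
    g[miss] = np.nan
    mu = np.nanmean(g, axis=0)
    inds = np.where(miss)
    g[inds] = np.take(mu, inds[1])
    p = mu / 2.0
    scale = np.sqrt(p * (1 - p))
    keep = scale > 0
    if not keep.any():
        raise PipelineError("genotype matrix has no variance")
    x = (g[:, keep] - mu[keep]) / scale[keep]
    m = x.shape[1]
    cov = x @ x.T / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(m * evals[:k])
    for j in range(k):  # deterministic sign: largest |coordinate| positive
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    frac = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    frame = pd.DataFrame(
        coords, index=list(sample_ids), columns=[f"PC{j+1}" for j in range(k)]
    )
    frame.index.name = "sample_id"
    return frame, frac[:k]
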