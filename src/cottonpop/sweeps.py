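"""Selective-sweep detection from window statistics.

Candidate domestication sweeps are the sliding windows that fall in the
top-q quantile (default q = 0.05) of *both* the landrace/cultivar
diversity ratio pi_L/pi_c and of the landrace-cultivar weighted Fst
(intersection by default; union mode behind a flag).  Thresholds are
computed over windows with defined values and are inclusive, so ties at
the threshold are selected.  Selected windows that overlap or book-end
merge into regions; region-level statistics are means over member
windows.

Between-species reuse of the same genomic regions is assessed with a
permutation test: one region set is repeatedly re-placed uniformly at
random on its own chromosomes (lengths preserved, overlaps among placed
regions allowed) and the observed intersection length is compared with
the permuted distribution, p = (1 + #{perm >= obs}) / (N + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomeLayout, PipelineError, log
from .variants import genes_in_intervals


def joint_top_quantile_scan(
    windows: pd.DataFrame,
    q: float = 0.05,
    mode: str = "and",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Select windows in the top-q tail of pi_ratio and of fst.

    ``windows`` must carry ``pi_ratio`` and ``fst`` columns (NaN = value
    undefined; such windows are excluded from ranking and selection).
    Returns (selected windows, thresholds used).
    """
    if not 0 < q < 1:
        raise PipelineError(f"quantile q must be in (0, 1), got {q}")
    if mode not in ("and", "or"):
        raise PipelineError(f"mode must be 'and' or 'or', got {mode!r}")
    defined = windows[np.isfinite(windows["pi_ratio"]) & np.isfinite(windows["fst"])]
    if len(defined) < 20:
        log.warning("only %d windows with defined statistics; quantile is unstable", len(defined))
    if defined.empty:
        return defined.copy(), {"pi_ratio": float("nan"), "fst": float("nan")}
    thr_ratio = float(np.quantile(defined["pi_ratio"], 1 - q))
    thr_fst = float(np.quantile(defined["fst"], 1 - q))
    top_ratio = defined["pi_ratio"] >= thr_ratio
    top_fst = defined["fst"] >= thr_fst
    sel = (top_ratio & top_fst) if mode == "and" else (top_ratio | top_fst)
    return defined[sel].copy(), {"pi_ratio": thr_ratio, "fst": thr_fst}


def merge_selected_windows(
    selected: pd.DataFrame, layout: GenomeLayout | None = None
) -> pd.DataFrame:
    """Merge overlapping / book-ended selected windows into sweep regions.

    Region statistics (mean pi_ratio, mean fst) are means over member
    windows; ``n_windows`` counts members.
    """
    cols = ["chrom", "start", "end", "n_windows", "mean_pi_ratio", "mean_fst"]
    if selected.empty:
        out = pd.DataFrame(columns=cols)
        if layout is not None:
            out["subgenome"] = pd.Series(dtype=str)
        return out
    sel = selected.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    cur = None
    members: list[int] = []

    def _flush():
        chunk = sel.loc[members]
        rows.append(
            (
                cur[0],
                cur[1],
                cur[2],
                len(members),
                float(chunk["pi_ratio"].mean()),
                float(chunk["fst"].mean()),
            )
        )

    for i, row in sel.iterrows():
        if cur is not None and row["chrom"] == cur[0] and row["start"] <= cur[2] + 1:
            cur = (cur[0], cur[1], max(cur[2], int(row["end"])))
            members.append(i)
        else:
            if cur is not None:
                _flush()
            cur = (row["chrom"], int(row["start"]), int(row["end"]))
            members = [i]
    _flush()
    out = pd.DataFrame(rows, columns=cols)
    if layout is not None:
        out["subgenome"] = out["chrom"].map(layout.subgenome_map())
    return out


# ---------------------------------------------------------------------------
# Interval arithmetic


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of 1-based inclusive intervals as sorted disjoint intervals."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1] + 1:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def overlap_bp(regions_a: pd.DataFrame, regions_b: pd.DataFrame) -> int:
    """Total bp of intersection between the unions of two region sets."""
    total = 0
    for chrom in set(regions_a["chrom"]) & set(regions_b["chrom"]):
        a = regions_a[regions_a["chrom"] == chrom]
        b = regions_b[regions_b["chrom"] == chrom]
        sa, ea = _merge_intervals(a["start"].to_numpy(), a["end"].to_numpy())
        sb, eb = _merge_intervals(b["start"].to_numpy(), b["end"].to_numpy())
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo <= hi:
                total += hi - lo + 1
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return int(total)


@dataclass
class OverlapTestResult:
    observed_overlap_bp: int
    permuted_overlaps: list[int]
    p_value: float
    n_permutations: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d) + "\n")


def overlap_permutation_test(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    layout: GenomeLayout,
    n_permutations: int = 1000,
    seed: int = 0,
    per_chromosome: bool = True,
) -> OverlapTestResult:
    """Permutation test for the overlap between two region sets.

    Set B's regions are re-placed with lengths preserved; by default each
    stays on its own chromosome (controlling for the A/D subgenome length
    asymmetry), optionally anywhere on the genome.  Placed regions may
    overlap each other.
    """
    if regions_a.empty or regions_b.empty:
        raise PipelineError("both region sets must be non-empty")
    lengths = (regions_b["end"] - regions_b["start"] + 1).to_numpy()
    chroms = regions_b["chrom"].to_numpy()
    for L, chrom in zip(lengths, chroms):
        if L > layout.length(chrom):
            raise PipelineError(f"region of {L} bp exceeds chromosome {chrom}")
    observed = overlap_bp(regions_a, regions_b)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_arr = layout.table["chrom"].to_numpy()
    len_arr = layout.table["length_bp"].to_numpy()
    probs = len_arr / len_arr.sum()

    # A's union per chromosome, precomputed once for the permutation loop
    a_union: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(regions_a["chrom"]):
        a = regions_a[regions_a["chrom"] == chrom]
        a_union[chrom] = _merge_intervals(a["start"].to_numpy(), a["end"].to_numpy())

    def _overlap_one(chrom: str, start: int, end: int) -> int:
        got = a_union.get(chrom)
        if got is None:
            return 0
        sa, ea = got
        lo = np.maximum(sa, start)
        hi = np.minimum(ea, end)
        return int(np.maximum(hi - lo + 1, 0).sum())

    perms = []
    for _ in range(n_permutations):
        if per_chromosome:
            new_chroms = chroms
        else:
            new_chroms = chrom_arr[rng.choice(len(chrom_arr), size=len(lengths), p=probs)]
        max_start = np.array([layout.length(c) for c in new_chroms]) - lengths + 1
        if (max_start < 1).any():
            raise PipelineError("region longer than the chromosome drawn for it")
        starts = rng.integers(1, max_start + 1)
        ends = starts + lengths - 1
        # placed regions may overlap each other; count intersection of the
        # placed union with A's union
        ps, pe = _merge_intervals(starts.copy(), ends.copy())
        total = 0
        for c in set(new_chroms) if len(set(new_chroms)) > 1 else [new_chroms[0]]:
            mask = new_chroms == c
            if mask.all():
                ms, me = ps, pe
            else:
                ms, me = _merge_intervals(starts[mask], ends[mask])
            for s, e in zip(ms, me):
                total += _overlap_one(c, int(s), int(e))
        perms.append(total)
    perms_arr = np.array(perms)
    p = (1 + int((perms_arr >= observed).sum())) / (n_permutations + 1)
    return OverlapTestResult(
        observed_overlap_bp=observed,
        permuted_overlaps=[int(x) for x in perms],
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def subgenome_summary(
    regions: pd.DataFrame,
    layout: GenomeLayout,
    annotation: GeneAnnotation | None = None,
) -> pd.DataFrame:
    """Region count, summed length (Mb), and overlapped-gene count per
    subgenome, plus a genome-wide total row."""
    sub = regions.get("subgenome")
    if sub is None:
        regions = regions.copy()
        regions["subgenome"] = regions["chrom"].map(layout.subgenome_map())
    gene_lists = None
    if annotation is not None:
        gene_lists = genes_in_intervals(
            list(zip(regions["chrom"], regions["start"], regions["end"])), annotation
        )
    rows = []
    for sub_name in ("A", "D"):
        mask = regions["subgenome"] == sub_name
        chunk = regions[mask]
        n_genes = 0
        if gene_lists is not None:
            genes = set()
            for i, use in enumerate(mask):
                if use:
                    genes.update(gene_lists[i])
            n_genes = len(genes)
        rows.append(
            (
                sub_name,
                int(len(chunk)),
                float((chunk["end"] - chunk["start"] + 1).sum() / 1e6),
                n_genes,
            )
        )
    total_genes = 0
    if gene_lists is not None:
        all_genes = set()
        for lst in gene_lists:
            all_genes.update(lst)
        total_genes = len(all_genes)
    rows.append(
        (
            "total",
            int(len(regions)),
            float((regions["end"] - regions["start"] + 1).sum() / 1e6),
            total_genes,
        )
    )
    return pd.DataFrame(rows, columns=["subgenome", "n_regions", "total_mb", "n_genes"])
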