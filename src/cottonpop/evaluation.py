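"""Truth-based evaluation of scan and tract calls on simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _interval_intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total bp of intersection between two interval lists (1-based incl.)."""
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                total += hi - lo + 1
    return total


def sweep_recovery(regions: pd.DataFrame, truth_sweeps: pd.DataFrame) -> dict:
    """Fraction of planted sweep regions intersected by >= 1 called region."""
    hit = 0
    for _, tr in truth_sweeps.iterrows():
        match = regions[
            (regions["chrom"] == tr["chrom"])
            & (regions["end"] >= tr["start"])
            & (regions["start"] <= tr["end"])
        ]
        if len(match):
            hit += 1
    n = len(truth_sweeps)
    return {"n_truth": n, "n_recovered": hit, "recovery": hit / n if n else float("nan")}


def tract_recovery(segments: pd.DataFrame, truth_tracts: pd.DataFrame) -> dict:
    """Base-level recall and precision of called introgression segments
    against planted tracts, aggregated over accessions."""
    inter = called_bp = truth_bp = 0
    samples = set(truth_tracts["sample_id"]) | (
        set(segments["sample_id"]) if len(segments) else set()
    )
    for sample in samples:
        for chrom in set(truth_tracts["chrom"]) | (
            set(segments["chrom"]) if len(segments) else set()
        ):
            t = truth_tracts[
                (truth_tracts["sample_id"] == sample) & (truth_tracts["chrom"] == chrom)
            ]
            c = (
                segments[
                    (segments["sample_id"] == sample) & (segments["chrom"] == chrom)
                ]
                if len(segments)
                else segments
            )
            t_iv = list(zip(t["start"], t["end"]))
            c_iv = list(zip(c["start"], c["end"])) if len(c) else []
            truth_bp += sum(e - s + 1 for s, e in t_iv)
            called_bp += sum(e - s + 1 for s, e in c_iv)
            inter += _interval_intersection(t_iv, c_iv)
    return {
        "recall": inter / truth_bp if truth_bp else float("nan"),
        "precision": inter / called_bp if called_bp else float("nan"),
        "truth_bp": truth_bp,
        "called_bp": called_bp,
        "intersect_bp": inter,
    }
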