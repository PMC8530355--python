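"""Interval-overlap permutation enrichment tests.

Do candidate gene sets (padded by +/- 20 kb) overlap outlier or desert
intervals more or less often than random placement would predict?  The null
re-places each gene uniformly on its own chromosome, preserving gene length
and allowing overlaps among shuffled genes (the behaviour of the standard
BED-shuffle tool), and recomputes the overlap count per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataValidationError, IntervalSet


@dataclass
class EnrichmentResult:
    """Observed overlap count vs. the permutation distribution."""

    observed_overlap: int
    perm_overlaps: np.ndarray
    p_greater: float
    p_less: float
    n_perm: int
    seed: int | None


def flank(genes: IntervalSet, pad_bp: int = 20_000, chrom_lengths=None) -> IntervalSet:
    """Extend every interval by ``pad_bp`` on both sides, clipped to bounds."""
    df = genes.records.copy()
    df["start_bp"] = (df["start_bp"] - pad_bp).clip(lower=0)
    if chrom_lengths is not None:
        df["end_bp"] = [
            min(e + pad_bp, chrom_lengths[c]) for e, c in zip(df["end_bp"], df["chrom"])
        ]
    else:
        df["end_bp"] = df["end_bp"] + pad_bp
    return IntervalSet(df)


def _merged_by_chrom(ivs: IntervalSet) -> dict:
    out = {}
    for chrom, grp in ivs.records.groupby("chrom", sort=False):
        s = grp["start_bp"].to_numpy(np.int64)
        e = grp["end_bp"].to_numpy(np.int64)
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        out[chrom] = (np.array(ms), np.array(me))
    return out


def _overlaps_merged(starts, ends, s, e):
    """Vector of bools: does [s_i, e_i) intersect the merged set (>= 1 bp)?"""
    s = np.asarray(s, np.int64)
    e = np.asarray(e, np.int64)
    # last interval with start < e; merged sets have increasing ends
    idx = np.searchsorted(starts, e, side="left") - 1
    hit = idx >= 0
    hit[hit] = ends[idx[hit]] > s[hit]
    return hit


def overlap_count(setA: IntervalSet, setB: IntervalSet) -> int:
    """Number of A-records intersecting any B-record (half-open semantics).

    An A-record counts once no matter how many B-records it touches;
    intersection requires at least one shared bp.
    """
    if len(setB) == 0 or len(setA) == 0:
        return 0
    merged = _merged_by_chrom(setB)
    count = 0
    for chrom, grp in setA.records.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        count += int(
            _overlaps_merged(ms, me, grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()).sum()
        )
    return count


def shuffle_test(
    genes: IntervalSet,
    targets: IntervalSet,
    chrom_lengths,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "within_chrom",
) -> EnrichmentResult:
    """Permutation test of gene/target interval overlap.

    Each permutation independently re-places every gene uniformly on its own
    chromosome, preserving its length (overlaps among shuffled genes are
    permitted), and counts genes overlapping the target set.  Pseudocount
    p-values: p_greater = (1 + #{perm >= obs}) / (1 + n_perm), p_less
    analogous; ties count toward both tails.
    """
    if mode != "within_chrom":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    for _, rec in genes.records.iterrows():
        glen = rec["end_bp"] - rec["start_bp"]
        if glen > chrom_lengths[rec["chrom"]]:
            raise DataValidationError(
                f"gene {rec['name']!r} is longer than chromosome {rec['chrom']}"
            )
    obs = overlap_count(genes, targets)
    rng = np.random.default_rng(seed)
    merged = _merged_by_chrom(targets) if len(targets) else {}
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, grp in genes.records.groupby("chrom", sort=False):
        lens = (grp["end_bp"] - grp["start_bp"]).to_numpy(np.int64)
        max_start = chrom_lengths[chrom] - lens  # inclusive upper bound
        starts = rng.integers(0, max_start + 1, size=(n_perm, len(lens)))
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        hits = _overlaps_merged(ms, me, starts.ravel(), (starts + lens).ravel())
        perm_counts += hits.reshape(n_perm, len(lens)).sum(axis=1)
    p_greater = float((1 + (perm_counts >= obs).sum()) / (1 + n_perm))
    p_less = float((1 + (perm_counts <= obs).sum()) / (1 + n_perm))
    return EnrichmentResult(
        observed_overlap=int(obs),
        perm_overlaps=perm_counts,
        p_greater=p_greater,
        p_less=p_less,
        n_perm=n_perm,
        seed=seed,
    )
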