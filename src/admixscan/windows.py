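"""Genetic-map hygiene, bp<->cM interpolation, 1 cM windows and quintiles.

A genetic map is a per-chromosome table of markers (pos_bp, pos_cM) that must
be strictly increasing in both coordinates after cleaning.  Interpolation is
piecewise-linear between markers; beyond the terminal markers the terminal
interval's recombination rate is extended to the chromosome ends, so every bp
on a chromosome has a cM position and vice versa.

Windows are successive 1 cM slices of each chromosome.  Each window carries
its recombination rate (cM/Mbp), coding-sequence overlap (bp and bp/cM) and
mean introgressed ancestry; windows are sorted into quintiles whose physical
extent each covers ~1/5 of the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AncestryMatrix, DataValidationError, IntervalSet


@dataclass
class GeneticMap:
    """Cleaned monotone marker map with terminal-rate extension.

    ``markers``: DataFrame (chrom, pos_bp, pos_cM), strictly increasing in
    both coordinates within each chromosome.  ``chrom_lengths`` gives bp
    lengths; interpolation anchors are augmented with virtual markers at bp 0
    and the chromosome end using the terminal intervals' rates.
    """

    markers: pd.DataFrame
    chrom_lengths: dict
    report: dict = field(default_factory=dict)
    _anchors: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy(float)
            cm = grp["pos_cM"].to_numpy(float)
            if len(bp) < 2:
                raise DataValidationError(f"chromosome {chrom}: < 2 markers")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise DataValidationError(f"chromosome {chrom}: map not monotone")
            length = float(self.chrom_lengths[chrom])
            rate_lo = (cm[1] - cm[0]) / (bp[1] - bp[0])
            rate_hi = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            abp = np.concatenate([[0.0], bp, [length]])
            acm = np.concatenate(
                [[cm[0] - rate_lo * bp[0]], cm, [cm[-1] + rate_hi * (length - bp[-1])]]
            )
            # drop degenerate duplicated anchors (marker at 0 or at the end)
            keep = np.concatenate([[True], np.diff(abp) > 0])
            self._anchors[chrom] = (abp[keep], acm[keep])

    @property
    def chromosomes(self) -> list:
        return list(self._anchors)

    def total_cM(self, chrom) -> float:
        abp, acm = self._anchors[chrom]
        return float(acm[-1] - acm[0])

    def interpolate_cM(self, chrom, pos_bp):
        """bp -> cM by linear interpolation (terminal-rate extrapolated)."""
        if chrom not in self._anchors:
            raise DataValidationError(f"unknown chromosome {chrom!r}")
        abp, acm = self._anchors[chrom]
        pos = np.asarray(pos_bp, float)
        out = np.interp(pos, abp, acm)
        return float(out) if out.ndim == 0 else out

    def interpolate_bp(self, chrom, pos_cM):
        """cM -> bp, the inverse interpolation (strictly monotone)."""
        if chrom not in self._anchors:
            raise DataValidationError(f"unknown chromosome {chrom!r}")
        abp, acm = self._anchors[chrom]
        pos = np.asarray(pos_cM, float)
        out = np.interp(pos, acm, abp)
        return float(out) if out.ndim == 0 else out


def _lis_lengths(values: np.ndarray) -> np.ndarray:
    """f[i] = length of the longest strictly-increasing subsequence ending at i."""
    n = len(values)
    tails: list[float] = []
    f = np.empty(n, dtype=int)
    for i, v in enumerate(values):
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        f[i] = lo + 1
        if lo == len(tails):
            tails.append(v)
        else:
            tails[lo] = v
    return f


def _longest_increasing_keep(values: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly-increasing subsequence.

    Among all maximal subsequences the earliest-marker one is kept (greedy
    left-to-right), so a later order-breaking marker is the one dropped when
    either choice would do — deterministic and stable in map order.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n == 0:
        return np.array([], dtype=int)
    f = _lis_lengths(values)
    g = _lis_lengths(-values[::-1])[::-1]  # longest strictly-increasing starting at i
    total = int((f + g - 1).max())
    keep = []
    last = -np.inf
    count = 0
    for i in range(n):
        if values[i] > last and count + g[i] >= total and f[i] >= count + 1:
            keep.append(i)
            last = values[i]
            count += 1
    return np.array(keep, dtype=int)


def clean_map(
    raw: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    exclude_markers: Sequence | None = None,
) -> GeneticMap:
    """Clean a raw lifted-over marker table into a monotone genetic map.

    Rules, applied in order (drops counted in ``report``):

    1. markers whose ``chrom`` differs from an optional ``map_chrom`` column
       (i.e. lifted to the wrong chromosome) are dropped;
    2. markers named in ``exclude_markers`` (complex rearranged regions that
       need manual curation) are dropped;
    3. within each chromosome (sorted by bp) the longest strictly-increasing
       cM subsequence is retained, which removes the minimal number of
       out-of-order markers and resolves simple local reversals;
    4. terminal recombination rates are extended to the chromosome ends
       (handled by :class:`GeneticMap` anchor construction).

    Chromosomes left with < 2 markers are excluded with a warning.
    """
    df = raw.copy()
    report = {"wrong_chromosome": 0, "excluded_list": 0, "out_of_order": 0,
              "chromosomes_dropped": []}
    if "map_chrom" in df.columns:
        bad = df["chrom"].astype(str) != df["map_chrom"].astype(str)
        report["wrong_chromosome"] = int(bad.sum())
        df = df[~bad]
    df = df[df["chrom"].isin(list(chrom_lengths))]
    if exclude_markers is not None and "name" in df.columns:
        bad = df["name"].isin(list(exclude_markers))
        report["excluded_list"] = int(bad.sum())
        df = df[~bad]
    kept = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp")
        # de-duplicate bp positions first (keep first)
        grp = grp[~grp["pos_bp"].duplicated()]
        idx = _longest_increasing_keep(grp["pos_cM"].to_numpy(float))
        report["out_of_order"] += len(grp) - len(idx)
        sub = grp.iloc[idx]
        if len(sub) < 2:
            report["chromosomes_dropped"].append(chrom)
            warnings.warn(f"chromosome {chrom} excluded: < 2 usable markers")
            continue
        kept.append(sub)
    markers = pd.concat(kept, ignore_index=True)[["chrom", "pos_bp", "pos_cM"]]
    lengths = {c: int(chrom_lengths[c]) for c in markers["chrom"].unique()}
    return GeneticMap(markers=markers, chrom_lengths=lengths, report=report)


def uniform_map(chrom_lengths: Mapping[str, int], rate_cM_per_Mbp: float = 0.75) -> GeneticMap:
    """A constant-rate map (useful default for simulation)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        rows.append((chrom, 1, rate_cM_per_Mbp * 1 / 1e6))
        rows.append((chrom, int(length), rate_cM_per_Mbp * length / 1e6))
    markers = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"])
    return GeneticMap(markers=markers, chrom_lengths=dict(chrom_lengths))


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms), np.array(me)


def coding_overlap_bp(window_start: int, window_end: int, starts: np.ndarray,
                      ends: np.ndarray) -> int:
    """Total bp of the merged intervals (starts, ends) inside [start, end)."""
    if len(starts) == 0:
        return 0
    lo = np.maximum(starts, window_start)
    hi = np.minimum(ends, window_end)
    return int(np.maximum(hi - lo, 0).sum())


def build_windows(
    gmap: GeneticMap,
    genes: IntervalSet | None,
    anc: AncestryMatrix | None,
    window_cM: float = 1.0,
) -> pd.DataFrame:
    """Tile each chromosome into successive ``window_cM`` windows.

    Returns a WindowTable DataFrame with columns chrom, start_bp, end_bp,
    cM_span, rec_rate (cM/Mbp), coding_bp, coding_bp_per_cM, mean_ancestry,
    n_loci, partial (final sub-window flag), quintile_rec, quintile_coding.
    Windows with zero ancestry loci have mean_ancestry = NaN.  Quintiles cut
    the metric-sorted windows at cumulative physical-bp fifths.
    """
    gene_iv: dict = {}
    if genes is not None and len(genes):
        for chrom, grp in genes.records.groupby("chrom", sort=False):
            gene_iv[chrom] = _merge_intervals(
                grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()
            )
    rows = []
    for chrom in gmap.chromosomes:
        length = gmap.chrom_lengths[chrom]
        cm0 = gmap.interpolate_cM(chrom, 0.0)
        cm1 = gmap.interpolate_cM(chrom, float(length))
        n_full = int(np.floor((cm1 - cm0) / window_cM))
        breaks_cm = cm0 + window_cM * np.arange(n_full + 1)
        if breaks_cm[-1] < cm1 - 1e-9:
            breaks_cm = np.append(breaks_cm, cm1)
        breaks_bp = np.round(gmap.interpolate_bp(chrom, breaks_cm)).astype(np.int64)
        breaks_bp[0], breaks_bp[-1] = 0, int(length)
        gs, ge = gene_iv.get(chrom, (np.array([]), np.array([])))
        for i in range(len(breaks_bp) - 1):
            s_bp, e_bp = int(breaks_bp[i]), int(breaks_bp[i + 1])
            if e_bp <= s_bp:
                continue
            cm_span = float(breaks_cm[i + 1] - breaks_cm[i])
            coding = coding_overlap_bp(s_bp, e_bp, gs, ge)
            rows.append(
                dict(
                    chrom=chrom,
                    start_bp=s_bp,
                    end_bp=e_bp,
                    cM_span=cm_span,
                    rec_rate=cm_span / ((e_bp - s_bp) / 1e6),
                    coding_bp=coding,
                    coding_bp_per_cM=coding / cm_span,
                    partial=cm_span < window_cM - 1e-9,
                )
            )
    win = pd.DataFrame(rows)
    # mean ancestry per window: loci assigned by bp (half-open windows; a
    # locus on a boundary belongs to the right window by construction)
    win["mean_ancestry"] = np.nan
    win["n_loci"] = 0
    if anc is not None:
        locus_mean = anc.freqs.to_numpy(float).mean(axis=1)
        for chrom, grp in anc.loci.groupby("chrom", sort=False):
            sel = win["chrom"] == chrom
            if not sel.any():
                continue
            wsub = win[sel]
            pos0 = grp["pos_bp"].to_numpy() - 1  # 1-based locus -> 0-based bp
            idx = np.searchsorted(wsub["start_bp"].to_numpy(), pos0, side="right") - 1
            ok = (idx >= 0) & (pos0 < wsub["end_bp"].to_numpy()[np.clip(idx, 0, None)])
            vals = locus_mean[grp.index.to_numpy()]
            for wi in np.unique(idx[ok]):
                mask = ok & (idx == wi)
                gi = wsub.index[wi]
                win.loc[gi, "mean_ancestry"] = float(vals[mask].mean())
                win.loc[gi, "n_loci"] = int(mask.sum())
    for metric, col in (("rec_rate", "quintile_rec"), ("coding_bp_per_cM", "quintile_coding")):
        win[col] = _bp_quintiles(win, metric)
    return win


def _bp_quintiles(win: pd.DataFrame, metric: str, k: int = 5) -> np.ndarray:
    """Assign quintile 0..k-1 by sorting on the metric and cutting at
    cumulative physical-bp fifths (each quintile ~1/5 of total bp)."""
    span = (win["end_bp"] - win["start_bp"]).to_numpy(float)
    order = np.argsort(win[metric].to_numpy(), kind="stable")
    cum = np.cumsum(span[order])
    total = cum[-1]
    mid = cum - span[order] / 2.0
    q_sorted = np.minimum((mid / (total / k)).astype(int), k - 1)
    q = np.empty(len(win), dtype=int)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Quintile / window correlations
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    level: str
    metric: str
    n_boot: int


def quintile_correlation(
    win: pd.DataFrame,
    metric: str = "rec_rate",
    level: str = "quintile",
    n_boot: int = 1000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rank correlation between a recombination metric and mean
    introgressed ancestry, with a window-bootstrap percentile CI.

    ``level='quintile'``: rho over the 5 (quintile rank, mean ancestry)
    pairs; bootstrap resamples 1 cM windows *within* quintiles.  Bootstrap
    replicates with tied quintile means are retained (average ranks).
    ``level='window'``: rho over individual windows; bootstrap resamples
    windows genomewide.
    """
    w = win.dropna(subset=["mean_ancestry"]).reset_index(drop=True)
    if w[metric].nunique() <= 1:
        raise DataValidationError(f"metric {metric!r} has no variation: rho undefined")
    rng = np.random.default_rng(seed)
    qcol = "quintile_rec" if metric == "rec_rate" else "quintile_coding"
    if level == "quintile":
        if w[qcol].nunique() < 2:
            raise DataValidationError("need >= 2 quintiles")
        groups = [w[w[qcol] == q]["mean_ancestry"].to_numpy() for q in sorted(w[qcol].unique())]
        qlev = np.array(sorted(w[qcol].unique()), float)
        rho = float(stats.spearmanr(qlev, [g.mean() for g in groups]).statistic)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            means = [g[rng.integers(0, len(g), len(g))].mean() for g in groups]
            boots[b] = stats.spearmanr(qlev, means).statistic
    elif level == "window":
        if len(w) < 10:
            raise DataValidationError("need >= 10 windows for window-level rho")
        x = w[metric].to_numpy(float)
        y = w["mean_ancestry"].to_numpy(float)
        rho = float(stats.spearmanr(x, y).statistic)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            i = rng.integers(0, len(x), len(x))
            boots[b] = stats.spearmanr(x[i], y[i]).statistic
    else:
        raise ValueError(f"unknown level {level!r}")
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return SpearmanResult(rho, float(lo), float(hi), level, metric, n_boot)
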