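"""Genome-wide per-locus selection scans on introgressed ancestry.

Two one-tailed scan families, each calibrated against the MVN null:

- mean-ancestry scan: the unweighted mean introgressed-ancestry frequency
  across populations at each locus; upper-tail outliers are adaptive
  introgression candidates, lower-tail outliers are introgression deficits;
- slope scan: the per-locus OLS slope of population ancestry frequency on
  elevation (per km); steep positive slopes mark loci where selection
  maintains an elevational cline.

Both statistics are computed identically on observed and simulated loci,
converted to pseudocount empirical p-values, and thresholded by
Benjamini–Hochberg at a grid of FDR levels.  Deserts (the genomewide lowest
introgression loci) and outlier intervals are derived from contiguous
qualifying loci with the halfway-extension rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import AncestryMatrix, DataValidationError, IntervalSet, PopulationSample
from .mvn import NullDraws, bh_fdr, empirical_pvalues

Q_GRID = (0.01, 0.05, 0.10)


@dataclass
class ScanResult:
    """Per-locus scan statistics, p-values, FDR decisions, and intervals."""

    table: pd.DataFrame  # per-locus: chrom, pos_bp, pos_cM, stat, p_upper, p_lower, reject_*
    statistic: str
    thresholds: dict = field(default_factory=dict)  # (tail, q) -> boundary stat value
    outliers: IntervalSet | None = None  # upper tail at reference q
    deserts: IntervalSet | None = None   # lower tail at reference q
    q_reference: float = 0.05


def loci_to_intervals(
    loci: pd.DataFrame,
    mask: np.ndarray,
    chrom_lengths: Mapping[str, int] | None = None,
    name: str = "interval",
) -> IntervalSet:
    """Merge flagged loci into 0-based half-open intervals.

    Each flagged locus spans halfway to its neighbours (chromosome ends clip
    to [0, length] when lengths are given, else to the terminal locus);
    adjacent flagged loci merge into one interval.
    """
    rows = []
    mask = np.asarray(mask, bool)
    for chrom, grp in loci.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy(float)
        sub = mask[grp.index.to_numpy()]
        if not sub.any():
            continue
        n = len(pos)
        left = np.empty(n)
        right = np.empty(n)
        left[1:] = (pos[:-1] + pos[1:]) / 2.0
        right[:-1] = left[1:]
        if chrom_lengths is not None:
            left[0], right[-1] = 0.0, float(chrom_lengths[chrom])
        else:
            left[0], right[-1] = pos[0] - 1.0, pos[-1]
        edges = np.diff(np.concatenate([[0], sub.view(np.int8), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0] - 1
        for s, e in zip(starts, ends):
            rows.append(
                (chrom, int(np.floor(left[s])), int(np.ceil(right[e])),
                 f"{name}_{chrom}_{int(pos[s])}")
            )
    return IntervalSet(pd.DataFrame(rows, columns=list(IntervalSet.COLUMNS)))


def _check_pops(anc: AncestryMatrix, null: NullDraws) -> None:
    if list(anc.populations) != list(null.populations):
        raise DataValidationError(
            "ancestry matrix and null draws have different population sets"
        )


def _scan(
    loci: pd.DataFrame,
    obs_stat: np.ndarray,
    null_stat: np.ndarray,
    statistic: str,
    q: float,
    chrom_lengths: Mapping[str, int] | None,
) -> ScanResult:
    p_up = empirical_pvalues(obs_stat, null_stat, tail="upper")
    p_lo = empirical_pvalues(obs_stat, null_stat, tail="lower")
    table = loci.copy()
    table["stat"] = obs_stat
    table["p_upper"] = p_up
    table["p_lower"] = p_lo
    thresholds = {}
    for qq in sorted(set(Q_GRID) | {q}):
        up, thr_up = bh_fdr(p_up, qq, stats=obs_stat, tail="upper")
        lo, thr_lo = bh_fdr(p_lo, qq, stats=obs_stat, tail="lower")
        tag = f"{qq:g}"
        table[f"reject_upper_q{tag}"] = up
        table[f"reject_lower_q{tag}"] = lo
        thresholds[("upper", qq)] = thr_up
        thresholds[("lower", qq)] = thr_lo
    tag = f"{q:g}"
    outliers = loci_to_intervals(
        loci, table[f"reject_upper_q{tag}"].to_numpy(), chrom_lengths, "outlier"
    )
    deserts = loci_to_intervals(
        loci, table[f"reject_lower_q{tag}"].to_numpy(), chrom_lengths, "deficit"
    )
    return ScanResult(
        table=table, statistic=statistic, thresholds=thresholds,
        outliers=outliers, deserts=deserts, q_reference=q,
    )


def mean_ancestry_scan(
    anc: AncestryMatrix,
    null: NullDraws,
    q: float = 0.05,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ScanResult:
    """Scan for loci with excess or deficit of mean introgressed ancestry.

    The statistic is the unweighted mean frequency across populations at each
    locus, computed identically for each simulated null locus.
    """
    _check_pops(anc, null)
    obs = anc.freqs.to_numpy(float).mean(axis=1)
    nul = null.sims.mean(axis=1)
    return _scan(anc.loci.reset_index(drop=True), obs, nul, "mean_ancestry", q, chrom_lengths)


def _ols_slopes(Y: np.ndarray, elev: np.ndarray) -> np.ndarray:
    """Row-wise OLS slope of Y (loci x pops) on elevation (km)."""
    ec = elev - elev.mean()
    denom = float(ec @ ec)
    return (Y - Y.mean(axis=1, keepdims=True)) @ ec / denom


def slope_scan(
    anc: AncestryMatrix,
    meta: Sequence[PopulationSample],
    null: NullDraws,
    q: float = 0.05,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ScanResult:
    """Scan for loci with steep ancestry-by-elevation clines.

    The per-locus statistic is the OLS slope (per km) of population ancestry
    frequency on elevation, populations weighted equally, intercept included.
    The same regression is applied to every simulated null locus with the
    same elevations, and both steep-positive and steep-negative tails are
    scanned one-tailed.
    """
    _check_pops(anc, null)
    by_id = {s.pop_id: s for s in meta}
    try:
        elev = np.array([by_id[p].elevation_km for p in anc.populations], float)
    except KeyError as e:
        raise DataValidationError(f"population {e} missing from metadata") from e
    if len(np.unique(elev)) < 3:
        raise DataValidationError("need >= 3 distinct elevations for the slope scan")
    obs = _ols_slopes(anc.freqs.to_numpy(float), elev)
    nul = _ols_slopes(null.sims, elev)
    return _scan(anc.loci.reset_index(drop=True), obs, nul, "elevation_slope", q, chrom_lengths)


def interaction_model(ind_table: pd.DataFrame, taxon: str | None = None) -> pd.DataFrame:
    """Fit ancestry ~ elevation + quintile + elevation:quintile by OLS.

    ``ind_table`` has one row per individual x recombination quintile with
    columns ``ancestry``, ``elevation_km``, ``quintile`` (numeric 0-4) and
    optionally ``taxon``.  A positive interaction coefficient means the
    ancestry-by-elevation cline steepens in higher-recombination quintiles.
    Returns a coefficient table (coef, se, p) for the four terms.
    """
    df = ind_table
    if taxon is not None:
        df = df[df["taxon"] == taxon]
    if df["quintile"].nunique() < 2:
        raise DataValidationError("need >= 2 quintiles to fit the interaction model")
    if df["elevation_km"].nunique() < 3:
        raise DataValidationError("need >= 3 distinct elevations")
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "elevation_km": df["elevation_km"].to_numpy(float),
            "quintile": df["quintile"].to_numpy(float),
        }
    )
    X["elevation_km:quintile"] = X["elevation_km"] * X["quintile"]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy()[:, 1:].T)
        pairs = [
            (X.columns[i + 1], X.columns[j + 1])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise DataValidationError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(df["ancestry"].to_numpy(float), X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )


def deserts(
    anc: AncestryMatrix,
    quantile: float = 0.05,
    chrom_lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Introgression deserts: the genomewide lowest-ancestry loci.

    The lowest ``quantile`` fraction of loci by cross-population mean
    ancestry (ties resolved by rank so at most ``floor(quantile * L)`` loci
    qualify, or all loci at quantile = 1), merged into intervals with the
    halfway-extension rule.
    """
    mean = anc.freqs.to_numpy(float).mean(axis=1)
    L = len(mean)
    k = L if quantile >= 1.0 else int(np.floor(quantile * L))
    mask = np.zeros(L, dtype=bool)
    if k > 0:
        order = np.argsort(mean, kind="stable")
        mask[order[:k]] = True
    return loci_to_intervals(anc.loci.reset_index(drop=True), mask, chrom_lengths, "desert")
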