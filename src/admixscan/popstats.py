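"""Allele-frequency population-genetic estimators.

Hudson's FST (ratio of averages, with the finite-sample corrections of
Bhatia et al.), the population branch statistic (PBS), the f4 statistic and
the f4-ratio admixture-proportion estimator with a block bootstrap, unbiased
per-site heterozygosity (pi), SNP site filters, and PBS-based ascertainment
of ancestry-informative markers (AIMs).

All estimators take plain per-site frequency/sample-size vectors or an
:class:`AlleleFreqPanel`, and are deliberately simple vectorized formulas so
that brute-force per-site reimplementations can confirm them exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import DataValidationError


class UndefinedStatistic(ValueError):
    """Raised when an estimator has no informative sites (0/0)."""


@dataclass
class AlleleFreqPanel:
    """Per-site allele frequencies and haploid sample sizes per population.

    ``sites``: DataFrame (chrom, pos_bp, pos_cM); ``freqs``: one column per
    population with derived-allele frequencies in [0, 1]; ``sizes``: mapping
    population -> per-site haploid sample-size array.
    """

    sites: pd.DataFrame
    freqs: pd.DataFrame
    sizes: Mapping[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> "AlleleFreqPanel":
        vals = self.freqs.to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise DataValidationError("panel frequency out of [0,1]")
        for pop in self.populations:
            if pop not in self.sizes:
                raise DataValidationError(f"no sample sizes for population {pop!r}")
        return self

    def p(self, pop: str) -> np.ndarray:
        return self.freqs[pop].to_numpy(float)

    def n(self, pop: str) -> np.ndarray:
        return np.asarray(self.sizes[pop], float)


# ---------------------------------------------------------------------------
# FST / PBS
# ---------------------------------------------------------------------------

def hudson_fst_components(p1, n1, p2, n2):
    """Per-site numerator and denominator of Hudson's FST.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites where both populations are monomorphic for the same allele have
    den = 0 (0/0) and must be excluded from both sums by the caller.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.broadcast_to(np.asarray(n1, float), p1.shape), np.broadcast_to(
        np.asarray(n2, float), p2.shape
    )
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson's FST combined across sites as a ratio of averages.

    Uninformative sites (both populations monomorphic for the same allele)
    are excluded from numerator and denominator sums.  Raises
    :class:`UndefinedStatistic` when no informative site remains.
    """
    num, den = hudson_fst_components(p1, n1, p2, n2)
    keep = den > 0
    if not keep.any():
        raise UndefinedStatistic("FST undefined: no informative sites")
    return float(num[keep].sum() / den[keep].sum())


def pbs(fst_12: float, fst_13: float, fst_23: float) -> float:
    """Population branch statistic for population 1.

    PBS = (T12 + T13 - T23) / 2 with T = -log(1 - FST).  Negative values are
    legitimate and returned as-is.  FST = 1 gives an infinite branch and is
    rejected.
    """
    for f in (fst_12, fst_13, fst_23):
        if f >= 1:
            raise UndefinedStatistic("FST >= 1 gives an infinite branch length")
    t12, t13, t23 = (-np.log1p(-f) for f in (fst_12, fst_13, fst_23))
    return float((t12 + t13 - t23) / 2.0)


def _per_site_fst(p1, n1, p2, n2) -> np.ndarray:
    """Per-site Hudson FST ratio (NaN where uninformative)."""
    num, den = hudson_fst_components(p1, n1, p2, n2)
    out = np.full(len(num), np.nan)
    keep = den > 0
    out[keep] = num[keep] / den[keep]
    return out


# ---------------------------------------------------------------------------
# f4 and the f4-ratio admixture estimator
# ---------------------------------------------------------------------------

@dataclass
class F4Result:
    """An f4 estimate with per-block means retained for the block bootstrap."""

    f4_value: float
    n_sites: int
    block_values: np.ndarray
    block_sums: np.ndarray
    block_counts: np.ndarray


def _block_ids(panel: AlleleFreqPanel, block_cM: float) -> np.ndarray:
    """Contiguous cM-window block label per site (for the block bootstrap)."""
    ids = np.empty(panel.n_sites, dtype=np.int64)
    offset = 0
    for chrom, grp in panel.sites.groupby("chrom", sort=False):
        cm = grp["pos_cM"].to_numpy(float)
        local = np.floor((cm - cm.min()) / block_cM).astype(np.int64)
        ids[grp.index.to_numpy()] = local + offset
        offset += local.max() + 1
    # compress to consecutive labels
    _, ids = np.unique(ids, return_inverse=True)
    return ids


def f4(panel: AlleleFreqPanel, quad: Sequence[str], block_cM: float = 1.0) -> F4Result:
    """f4(A, B; C, D) = mean over sites of (pA - pB)(pC - pD).

    The sign convention matches the negative of the ABBA-BABA numerator
    divided by the number of sites: shared drift between the (A, B) and
    (C, D) pairs.  Sites with missing data (NaN) in any of the four
    populations are excluded; per-block means over ``block_cM`` map windows
    are kept for bootstrapping.
    """
    a, b, c, d = (panel.p(q) for q in quad)
    prod = (a - b) * (c - d)
    keep = np.isfinite(prod)
    if not keep.any():
        raise UndefinedStatistic("f4 undefined: no complete sites")
    ids = _block_ids(panel, block_cM)
    nb = ids.max() + 1
    sums = np.bincount(ids[keep], weights=prod[keep], minlength=nb)
    counts = np.bincount(ids[keep], minlength=nb)
    with np.errstate(invalid="ignore"):
        block_values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return F4Result(
        f4_value=float(prod[keep].mean()),
        n_sites=int(keep.sum()),
        block_values=block_values,
        block_sums=sums,
        block_counts=counts,
    )


@dataclass
class AlphaEstimate:
    """f4-ratio admixture-proportion estimate with a percentile bootstrap CI."""

    alpha: float
    ci_low: float
    ci_high: float
    numerator: float
    denominator: float
    n_boot: int
    n_sites: int


def f4_ratio_alpha(
    panel: AlleleFreqPanel,
    focal_X: str = "focal",
    block_cM: float = 1.0,
    n_boot: int = 500,
    seed: int | None = None,
    denom_tol: float = 1e-6,
) -> AlphaEstimate:
    """Admixture proportion alpha from a ratio of two f4 statistics.

    alpha = f4(outgroup, parviglumis; X, maize)
          / f4(outgroup, parviglumis; mexicana, maize)

    estimates the proportion of X's ancestry inherited from the mexicana
    side of the reference tree.  The CI is a percentile bootstrap over
    ``block_cM`` map blocks, resampled jointly for numerator and denominator.
    """
    num = f4(panel, ("outgroup", "parviglumis", focal_X, "maize"), block_cM)
    den = f4(panel, ("outgroup", "parviglumis", "mexicana", "maize"), block_cM)
    if abs(den.f4_value) < denom_tol:
        raise UndefinedStatistic(
            f"f4-ratio denominator {den.f4_value} is within {denom_tol} of zero"
        )
    alpha = num.f4_value / den.f4_value
    rng = np.random.default_rng(seed)
    nb = len(num.block_sums)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, nb, nb)
        ns = num.block_sums[idx].sum()
        ds = den.block_sums[idx].sum()
        boots[i] = ns / ds if ds != 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return AlphaEstimate(
        alpha=float(alpha), ci_low=float(lo), ci_high=float(hi),
        numerator=num.f4_value, denominator=den.f4_value,
        n_boot=n_boot, n_sites=num.n_sites,
    )


# ---------------------------------------------------------------------------
# Diversity, site filters, AIMs
# ---------------------------------------------------------------------------

def pi_within(p, n) -> tuple[np.ndarray, float]:
    """Unbiased per-site expected heterozygosity 2 p (1-p) n/(n-1).

    Returns (per-site pi, mean over assayed sites).  Sites with n < 2 are
    skipped (NaN) and excluded from the mean; monomorphic sites contribute 0.
    """
    p = np.asarray(p, float)
    n = np.broadcast_to(np.asarray(n, float), p.shape)
    out = np.full(p.shape, np.nan)
    ok = n >= 2
    out[ok] = 2.0 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1)
    if not ok.any():
        raise UndefinedStatistic("pi undefined: all sites have n < 2")
    if (~ok).any():
        warnings.warn(f"pi_within: skipped {int((~ok).sum())} sites with n < 2")
    return out, float(out[ok].mean())


def filter_sites(
    table: pd.DataFrame,
    maf_min: float = 0.05,
    n_min: int = 150,
    depth_factor: float = 2.5,
    mean_depth: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the SNP site filters used for low-coverage variant discovery.

    Keeps sites with minor allele frequency >= ``maf_min``, at least
    ``n_min`` individuals with data, and total depth not *exceeding*
    ``depth_factor`` x the sample mean depth (strict >; a site exactly at
    the cutoff is kept).  ``table`` needs columns ``maf``, ``n_with_data``,
    ``total_depth``.  Returns (filtered table, per-rule removal report).
    """
    if len(table) == 0:
        warnings.warn("filter_sites: empty input")
        return table.copy(), {"maf": 0, "n_with_data": 0, "depth": 0, "kept": 0}
    if mean_depth is None:
        mean_depth = float(table["total_depth"].mean())
    pass_maf = table["maf"].to_numpy(float) >= maf_min
    pass_n = table["n_with_data"].to_numpy() >= n_min
    pass_depth = ~(table["total_depth"].to_numpy(float) > depth_factor * mean_depth)
    keep = pass_maf & pass_n & pass_depth
    report = {
        "maf": int((~pass_maf).sum()),
        "n_with_data": int((~pass_n).sum()),
        "depth": int((~pass_depth).sum()),
        "kept": int(keep.sum()),
        "mean_depth": mean_depth,
    }
    return table[keep].copy(), report


def _nearest_rank_quantile(x: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: smallest value with cdf >= q."""
    xs = np.sort(x)
    k = int(np.ceil(q * len(xs))) - 1
    return float(xs[max(k, 0)])


def ascertain_aims(
    panel: AlleleFreqPanel,
    top_fraction: float = 0.10,
    min_spacing_cM: float = 0.001,
    reference_pops: Sequence[str] = ("maize", "mexicana", "parviglumis"),
) -> pd.DataFrame:
    """Ascertain ancestry-informative markers by top-tail PBS.

    Per-site PBS is computed with each of the three reference populations as
    the focal branch; a site qualifies when it falls in the top
    ``top_fraction`` tail of *any* configuration (nearest-rank threshold,
    ties >= kept).  Qualifying sites are then thinned by a greedy walk in cM
    order per chromosome, keeping a site only if it lies at least
    ``min_spacing_cM`` beyond the last kept site (first qualifying site in
    map order kept; ties broken by bp).  Returns the retained site table.
    """
    if panel.n_sites < 10:
        raise DataValidationError("fewer than 10 sites: top-tail quantile unstable")
    a, b, c = reference_pops
    fab = _per_site_fst(panel.p(a), panel.n(a), panel.p(b), panel.n(b))
    fac = _per_site_fst(panel.p(a), panel.n(a), panel.p(c), panel.n(c))
    fbc = _per_site_fst(panel.p(b), panel.n(b), panel.p(c), panel.n(c))
    with np.errstate(divide="ignore", invalid="ignore"):
        T = {k: -np.log1p(-np.minimum(v, 1.0)) for k, v in
             (("ab", fab), ("ac", fac), ("bc", fbc))}
    pbs_site = {
        a: (T["ab"] + T["ac"] - T["bc"]) / 2,
        b: (T["ab"] + T["bc"] - T["ac"]) / 2,
        c: (T["ac"] + T["bc"] - T["ab"]) / 2,
    }
    qual = np.zeros(panel.n_sites, dtype=bool)
    for focal, vals in pbs_site.items():
        ok = np.isfinite(vals) | np.isposinf(vals)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            continue
        thr = _nearest_rank_quantile(finite, 1 - top_fraction)
        qual |= ok & (vals >= thr)
    sites = panel.sites.copy()
    sites["qualifies"] = qual
    kept_idx = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        grp = grp.sort_values(["pos_cM", "pos_bp"], kind="stable")
        last = -np.inf
        for idx, row in grp.iterrows():
            if not row["qualifies"]:
                continue
            if row["pos_cM"] - last >= min_spacing_cM or min_spacing_cM == 0:
                kept_idx.append(idx)
                last = row["pos_cM"]
    if min_spacing_cM == 0:
        kept_idx = list(sites.index[qual])
    return sites.loc[sorted(kept_idx)].drop(columns="qualifies")
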