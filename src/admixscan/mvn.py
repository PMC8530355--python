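"""The multivariate-normal null model for ancestry-frequency scans.

Genomewide, each population's introgressed-ancestry frequency at a locus
fluctuates around its mean through drift and shared post-admixture history.
The null model captures exactly those two moments: the per-population mean
vector alpha and the between-population covariance matrix K, estimated from
all loci, and then simulates unlinked loci as draws from MVN(alpha, K)
truncated (clamped) to [0, 1].  Observed per-locus statistics are converted
to empirical one-tailed p-values against the same statistic computed on the
simulated loci, and Benjamini–Hochberg controls the false-discovery rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datamodel import AncestryMatrix, DataValidationError

logger = logging.getLogger(__name__)


@dataclass
class AncestryCovariance:
    """Genomewide ancestry mean vector and P x P covariance matrix."""

    alpha: np.ndarray
    K: np.ndarray
    n_loci_used: int
    populations: list


@dataclass
class NullDraws:
    """Simulated null ancestry frequencies (n_sim x P), clamped to [0, 1]."""

    sims: np.ndarray
    seed: int | None
    truncated_fraction: float
    populations: list


def estimate_K(anc: AncestryMatrix) -> AncestryCovariance:
    """Estimate (alpha, K) from an ancestry matrix.

    alpha_i is population i's mean frequency over loci; K[i, j] =
    (1/L) sum_l (Anc_il - alpha_i)(Anc_jl - alpha_j), i.e. the population
    (1/L) normalizer, not the sample (1/(L-1)) one.  Loci with any missing
    frequency are dropped listwise (count reported via logging).
    """
    X = anc.freqs.to_numpy(float)
    keep = np.isfinite(X).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("estimate_K: dropped %d loci with missing frequencies", dropped)
    X = X[keep]
    if len(X) < 2:
        raise DataValidationError("need at least 2 complete loci to estimate K")
    alpha = X.mean(axis=0)
    D = X - alpha
    K = D.T @ D / len(X)
    zero_var = np.diag(K) <= 1e-20  # constant columns up to float round-off
    if zero_var.any():
        pops = [p for p, z in zip(anc.populations, zero_var) if z]
        warnings.warn(f"populations with zero ancestry variance: {pops}")
    return AncestryCovariance(
        alpha=alpha, K=K, n_loci_used=int(len(X)), populations=anc.populations
    )


def simulate_null(
    cov: AncestryCovariance, n_sim: int = 100_000, seed: int | None = None
) -> NullDraws:
    """Draw ``n_sim`` unlinked loci from MVN(alpha, K), clamped to [0, 1].

    If the Cholesky factorization fails, a jitter eps*I is added with eps
    escalating 1e-12 -> 1e-8 (logged); persistent failure raises.  The
    fraction of entries clamped is recorded on the result.
    """
    rng = np.random.default_rng(seed)
    P = len(cov.alpha)
    K = np.asarray(cov.K, float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise DataValidationError("K must be symmetric")
    if np.all(K == 0):
        draws = np.tile(cov.alpha, (n_sim, 1))
        return NullDraws(np.clip(draws, 0, 1), seed, 0.0, cov.populations)
    chol = None
    for eps in (0.0, 1e-12, 1e-11, 1e-10, 1e-9, 1e-8):
        try:
            chol = np.linalg.cholesky(K + eps * np.eye(P))
            if eps > 0:
                logger.info("simulate_null: added jitter %.0e to K diagonal", eps)
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise np.linalg.LinAlgError(
            "K is not positive semi-definite even after 1e-8 jitter"
        )
    draws = cov.alpha + rng.standard_normal((n_sim, P)) @ chol.T
    truncated = float(np.mean((draws < 0) | (draws > 1)))
    return NullDraws(np.clip(draws, 0.0, 1.0), seed, truncated, cov.populations)


def empirical_pvalues(obs_stats, null_stats, tail: str = "upper") -> np.ndarray:
    """Pseudocount empirical p-values of observed statistics against a null.

    Upper tail: p = (1 + #{null >= obs}) / (1 + n_sim); lower tail mirrors.
    Ties count toward the tail (conservative); NaN observations stay NaN
    (count logged).  Monotone nonincreasing in obs for the upper tail.
    """
    obs = np.asarray(obs_stats, float)
    null = np.asarray(null_stats, float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise DataValidationError("null_stats is empty")
    nan = ~np.isfinite(obs)
    if nan.any():
        logger.info("empirical_pvalues: %d NaN observed statistics", int(nan.sum()))
    ns = np.sort(null)
    n = len(ns)
    p = np.full(obs.shape, np.nan)
    ok = ~nan
    if tail == "upper":
        ge = n - np.searchsorted(ns, obs[ok], side="left")
        p[ok] = (1.0 + ge) / (1.0 + n)
    elif tail == "lower":
        le = np.searchsorted(ns, obs[ok], side="right")
        p[ok] = (1.0 + le) / (1.0 + n)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return p


def bh_fdr(p, q: float = 0.05, stats=None, tail: str = "upper"):
    """Benjamini–Hochberg step-up decisions at FDR level ``q``.

    Returns ``(reject, stat_threshold)``: boolean decisions aligned with the
    input (NaN p-values are never rejected) and, when per-locus ``stats`` are
    supplied, the statistic value at the decision boundary — the least
    extreme rejected value (min for an upper-tail scan, max for lower) — or
    NaN if nothing is rejected.
    """
    p = np.asarray(p, float)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        reject[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    thr = np.nan
    if stats is not None and reject.any():
        s = np.asarray(stats, float)[reject]
        thr = float(s.min() if tail == "upper" else s.max())
    return reject, thr
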