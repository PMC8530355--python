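"""Introgression-peak calling and peak sharing across populations.

A peak locus for a population is one whose introgressed-ancestry frequency
exceeds that population's genomewide mean by more than ``sd_mult`` standard
deviations (strict >, s.d. over loci with the population 1/L normalizer, the
same normalizer as the K-matrix diagonal so thresholds and covariance are
mutually consistent).  Sharing between a set of populations is the fraction
of all genomewide loci flagged in every member; the MVN null, classified by
the *empirical* thresholds, gives the sharing expected from shared drift and
gene flow alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import AncestryMatrix, DataValidationError
from .mvn import AncestryCovariance, simulate_null


@dataclass
class PeakCalls:
    """Boolean peak flags (loci x populations) and per-population thresholds."""

    flags: pd.DataFrame
    thresholds: pd.Series
    sd_mult: float


@dataclass
class SharingNetwork:
    """Fractions of genomewide loci inside shared ancestry peaks.

    ``combos``: one row per population pair/combination up to ``combos_max``
    members, with the shared fraction and (for null networks) the expected
    value and a percentile band.  ``observed_sets`` ranks the exact flagged
    population sets by frequency.
    """

    combos: pd.DataFrame
    observed_sets: pd.DataFrame | None = None
    n_loci: int = 0
    meta: dict = field(default_factory=dict)

    def pair_frame(self) -> pd.DataFrame:
        return self.combos[self.combos["size"] == 2].reset_index(drop=True)


def call_peaks(anc: AncestryMatrix, sd_mult: float = 2.0) -> PeakCalls:
    """Flag per-population peak loci above mean + sd_mult * s.d. (strict >)."""
    X = anc.freqs.to_numpy(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)  # population normalizer, consistent with K
    zero = sd <= 1e-12  # constant columns up to float round-off
    if zero.any():
        pops = [p for p, z in zip(anc.populations, zero) if z]
        warnings.warn(f"zero-variance populations have no peaks: {pops}")
    thr = mean + sd_mult * sd
    flags = X > thr
    flags[:, zero] = False
    return PeakCalls(
        flags=pd.DataFrame(flags, columns=anc.populations),
        thresholds=pd.Series(thr, index=anc.populations),
        sd_mult=sd_mult,
    )


def classify_by_thresholds(sims: np.ndarray, thresholds: pd.Series) -> pd.DataFrame:
    """Apply empirical peak thresholds to simulated loci (strict >)."""
    return pd.DataFrame(
        sims > thresholds.to_numpy()[None, :], columns=list(thresholds.index)
    )


def sharing(flags: pd.DataFrame, combos_max: int = 5) -> SharingNetwork:
    """Peak-sharing fractions for all pairs and combinations up to ``combos_max``.

    The denominator is all genomewide loci.  ``observed_sets`` additionally
    ranks the exact sets of populations flagged together locus-by-locus,
    avoiding the 2^P blowup of full enumeration.
    """
    F = flags.to_numpy(bool)
    L, P = F.shape
    pops = list(flags.columns)
    rows = []
    for size in range(1, min(combos_max, P) + 1):
        for combo in combinations(range(P), size):
            frac = float(F[:, combo].all(axis=1).mean()) if L else 0.0
            rows.append(
                {"combo": tuple(pops[i] for i in combo), "size": size, "fraction": frac}
            )
    combos = pd.DataFrame(rows)
    # exact observed peak-population sets, ranked by frequency
    sets: dict = {}
    any_flag = F.any(axis=1)
    for row in F[any_flag]:
        key = tuple(p for p, f in zip(pops, row) if f)
        sets[key] = sets.get(key, 0) + 1
    observed = pd.DataFrame(
        [{"set": k, "size": len(k), "count": v, "fraction": v / L} for k, v in sets.items()]
    )
    if len(observed):
        observed = observed.sort_values("count", ascending=False).reset_index(drop=True)
    return SharingNetwork(combos=combos, observed_sets=observed, n_loci=L)


def null_sharing(
    cov: AncestryCovariance,
    thresholds: pd.Series,
    n_sim: int = 100_000,
    seed: int | None = None,
    n_obs_loci: int | None = None,
    n_boot: int = 200,
    combos_max: int = 5,
    band: tuple = (2.5, 97.5),
) -> SharingNetwork:
    """Expected peak sharing under the MVN null with empirical thresholds.

    Simulated loci are classified by the thresholds from the *observed* data;
    sharing is computed identically.  The percentile band per combination
    comes from resampling ``n_obs_loci`` loci (default: the number of
    observed loci, so the band reflects the sampling noise of an empirical
    sharing fraction) from the simulated pool, ``n_boot`` times.
    """
    if list(thresholds.index) != list(cov.populations):
        raise DataValidationError("thresholds and covariance populations differ")
    draws = simulate_null(cov, n_sim=n_sim, seed=seed)
    flags = classify_by_thresholds(draws.sims, thresholds)
    net = sharing(flags, combos_max=combos_max)
    n_res = n_sim if n_obs_loci is None else int(n_obs_loci)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    F = flags.to_numpy(bool)
    pops = list(flags.columns)
    # per-combination AND columns once; bootstrap means over resampled loci
    combo_list = list(net.combos["combo"])
    and_cols = np.empty((n_sim, len(combo_list)), dtype=bool)
    index_of = {p: i for i, p in enumerate(pops)}
    for j, combo in enumerate(combo_list):
        and_cols[:, j] = F[:, [index_of[p] for p in combo]].all(axis=1)
    lo = np.empty(len(combo_list))
    hi = np.empty(len(combo_list))
    boot_means = np.empty((n_boot, len(combo_list)))
    for b in range(n_boot):
        idx = rng.integers(0, n_sim, n_res)
        boot_means[b] = and_cols[idx].mean(axis=0)
    lo[:], hi[:] = np.percentile(boot_means, band, axis=0)
    net.combos["band_low"] = lo
    net.combos["band_high"] = hi
    net.meta = {
        "n_sim": n_sim, "n_obs_loci": n_res, "n_boot": n_boot,
        "seed": seed, "truncated_fraction": draws.truncated_fraction,
    }
    return net
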