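"""Synthetic pulse-admixture data generator.

Everything downstream (scans, peak sharing, f4/FST estimators, enrichment)
is exercised against data from this module, which emulates the study design
the package targets: 14 sympatric admixed populations sampled along an
elevational gradient, low-coverage sequencing, and a two-pulse admixture
history (an admixed population founded by *mexicana* receives a pulse of
*parviglumis* ancestry and a pulse of maize ancestry).

Four generators, all pure functions of (config, seed):

- :func:`simulate_ancestry_frequencies` — per-locus introgressed-ancestry
  frequencies across populations drawn from a truncated multivariate normal
  with an elevational cline in the means and a drift covariance ``K``; loci
  carrying planted selection signals (mean shifts, steep clines) are recorded
  in truth records for parameter-recovery tests.
- :func:`simulate_diploid_tracts` — haploid ancestry tracts as a Markov jump
  process along the genetic map whose switch intensities are set by the pulse
  ages, paired into diploid 6-state posteriors.
- :func:`simulate_reference_panels` — Balding–Nichols allele-frequency
  divergence on the reference tree (((parviglumis, maize), mexicana),
  outgroup), plus an admixed focal population mixing the sources, so f4, FST
  and PBS have known expectations.
- :func:`emit_read_counts` — Poisson-depth binomial read counts emulating
  ~1x coverage data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ANCESTRIES, AncestryMatrix, DataValidationError, DiploidPosterior, DIPLOID_STATES
from .popstats import AlleleFreqPanel
from .windows import GeneticMap, uniform_map

#: Age (generations) of the founding ancestry in the two-pulse model.
FOUNDING_AGE = 10_000.0


def _default_elevations(n: int) -> list[float]:
    # sampled sites span 1.547-2.600 km
    return list(np.round(np.linspace(1.547, 2.600, n), 3))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the target study design: 14 sympatric populations
    along a 1.55-2.60 km elevational gradient, mean introgressed ancestry
    rising 0.22 per km, admixture pulses ~1014 (maize) and ~173
    (*parviglumis*) generations ago, and ~1x sequencing coverage.

    ``K_scale``/``K_shared`` imply the drift covariance
    ``K = K_scale * [(1-K_shared) I + K_shared 11']`` (always PSD).
    """

    seed: int = 0
    n_pops: int = 14
    elevations_km: Sequence[float] = field(default_factory=lambda: _default_elevations(14))
    n_chrom: int = 10
    chrom_len_bp: int = 200_000_000
    n_loci: int = 10_000
    alpha_base: float = -0.20          # intercept of mean ancestry (at 0 km)
    beta_elev: float = 0.22            # clinal slope of mean ancestry per km
    K_scale: float = 0.0025            # drift variance scale (sd 0.05)
    K_shared: float = 0.3              # fraction of variance shared across pops
    t_maize: float = 1014.0            # generations since maize pulse
    t_parv: float = 173.0              # generations since parviglumis pulse
    mix_maize: float = 0.75            # maize pulse proportion
    mix_parv: float = 0.05             # parviglumis pulse proportion
    coverage_mean: float = 1.0         # mean sequencing depth
    n_ind_per_pop: int = 10
    fst_ref: float = 0.1               # divergence of reference panels
    n_clinal_loci: int = 0             # loci planted with an extra slope
    n_outlier_loci: int = 0            # loci planted with a mean shift
    planted_slope: float = 0.8         # per km
    planted_shift: float = 0.15

    def validate(self) -> "SimConfig":
        if len(self.elevations_km) != self.n_pops:
            raise DataValidationError(
                f"elevations_km has {len(self.elevations_km)} entries, expected n_pops={self.n_pops}"
            )
        if any(e <= 0 for e in self.elevations_km):
            raise DataValidationError("elevations_km must be strictly positive")
        if not (self.mix_maize + self.mix_parv <= 1 + 1e-12):
            raise DataValidationError("mix_maize + mix_parv must be <= 1")
        if self.K_scale < 0:
            raise DataValidationError("K_scale must be >= 0")
        if not (0 <= self.K_shared < 1):
            raise DataValidationError("K_shared must be in [0, 1)")
        if not (0 < self.fst_ref < 1):
            raise DataValidationError("fst_ref must be in (0, 1)")
        if self.n_clinal_loci + self.n_outlier_loci > self.n_loci:
            raise DataValidationError("more planted loci than loci")
        return self

    @property
    def pop_ids(self) -> list[str]:
        return [f"pop{i:02d}" for i in range(self.n_pops)]

    @property
    def chrom_lengths(self) -> dict:
        return {f"chr{i + 1}": self.chrom_len_bp for i in range(self.n_chrom)}

    def implied_K(self) -> np.ndarray:
        """Drift covariance implied by (K_scale, K_shared)."""
        P = self.n_pops
        return self.K_scale * (
            (1 - self.K_shared) * np.eye(P) + self.K_shared * np.ones((P, P))
        )

    def mean_ancestry(self) -> np.ndarray:
        """Per-population genomewide mean ancestry: alpha_base + beta_elev*elev."""
        return self.alpha_base + self.beta_elev * np.asarray(self.elevations_km, float)

    def default_map(self, rate_cM_per_Mbp: float = 0.75) -> GeneticMap:
        return uniform_map(self.chrom_lengths, rate_cM_per_Mbp)


def _locus_positions(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spaced 1-based locus positions across the chromosomes."""
    per = np.full(cfg.n_chrom, cfg.n_loci // cfg.n_chrom)
    per[: cfg.n_loci % cfg.n_chrom] += 1
    gmap = cfg.default_map()
    frames = []
    for (chrom, length), k in zip(cfg.chrom_lengths.items(), per):
        if k == 0:
            continue
        pos = np.linspace(1, length, int(k), dtype=np.int64)
        pos = np.unique(pos)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos_bp": pos, "pos_cM": gmap.interpolate_cM(chrom, pos.astype(float))}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ancestry_frequencies(
    cfg: SimConfig,
    empirical: AncestryMatrix | None = None,
) -> tuple[AncestryMatrix, pd.DataFrame]:
    """Draw per-locus ancestry frequencies for all populations.

    Parametric mode (default): each locus is an independent Gaussian vector
    with mean ``alpha_base + beta_elev * elevation`` (per population) and
    covariance ``implied_K()``, truncated (clamped) to [0, 1] after the draw.
    Planted loci perturb the mean: ``high_mean`` / ``low_mean`` loci shift all
    populations by +/- ``planted_shift``; ``steep_slope`` loci add
    ``planted_slope * (elev - mean(elev))`` so the locus mean stays put while
    its cline steepens.

    Empirical-resample mode: if ``empirical`` is given, loci are resampled
    with replacement from its rows instead of drawn parametrically (no
    planted loci).

    Returns ``(matrix, truth)`` where ``truth`` has one row per locus
    (locus_id, planted_class, true alpha vector columns).  The realized
    truncated fraction is stored in ``matrix.meta['truncated_fraction']``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loci = _locus_positions(cfg)
    L, P = len(loci), cfg.n_pops
    elev = np.asarray(cfg.elevations_km, float)

    if empirical is not None:
        idx = rng.integers(0, empirical.n_loci, L)
        vals = empirical.freqs.to_numpy(float)[idx]
        freqs = pd.DataFrame(vals, columns=empirical.populations)
        truth = pd.DataFrame(
            {"locus_id": np.arange(L), "planted_class": "null"}
        )
        mat = AncestryMatrix(
            loci=loci, freqs=freqs, meta={"mode": "empirical", "truncated_fraction": 0.0}
        )
        return mat.validate(), truth

    K = cfg.implied_K()
    # eigendecomposition is safe for the always-PSD implied K; reject others
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise DataValidationError("implied covariance is not positive semi-definite")

    means = np.tile(cfg.mean_ancestry(), (L, 1))
    classes = np.array(["null"] * L, dtype=object)
    planted = rng.choice(L, size=cfg.n_outlier_loci + cfg.n_clinal_loci, replace=False)
    out_idx = planted[: cfg.n_outlier_loci]
    cli_idx = planted[cfg.n_outlier_loci:]
    half = len(out_idx) // 2
    hi, lo = out_idx[: len(out_idx) - half], out_idx[len(out_idx) - half:]
    means[hi] += cfg.planted_shift
    means[lo] -= cfg.planted_shift
    classes[hi], classes[lo] = "high_mean", "low_mean"
    means[cli_idx] += cfg.planted_slope * (elev - elev.mean())
    classes[cli_idx] = "steep_slope"

    if cfg.K_scale == 0:
        draws = means.copy()
    else:
        chol = np.linalg.cholesky(K + 1e-15 * np.eye(P))
        draws = means + rng.standard_normal((L, P)) @ chol.T
    truncated = float(np.mean((draws < 0) | (draws > 1)))
    draws = np.clip(draws, 0.0, 1.0)

    freqs = pd.DataFrame(draws, columns=cfg.pop_ids)
    truth = pd.DataFrame({"locus_id": np.arange(L), "planted_class": classes})
    for j, pid in enumerate(cfg.pop_ids):
        truth[f"true_alpha_{pid}"] = means[:, j]
    mat = AncestryMatrix(
        loci=loci,
        freqs=freqs,
        meta={"mode": "parametric", "seed": cfg.seed, "truncated_fraction": truncated},
    )
    return mat.validate(), truth


# ---------------------------------------------------------------------------
# Diploid tracts under the two-pulse Markov model
# ---------------------------------------------------------------------------

def _transition_rates(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-Morgan switch rates between ancestries.

    State order follows :data:`ANCESTRIES` = (maize, mexicana, parviglumis).
    The rate from ancestry a to b is ``min(t_a, t_b) * m_b``: recombination
    events since the most recent of the two pulses can swap the local
    ancestry, and the swap lands in b with probability equal to b's genomewide
    proportion (the same single-pulse approximation the forward HMM model
    makes for each pulse).  The chain is reversible with stationary
    distribution equal to the mixing proportions.
    """
    m = np.array(
        [cfg.mix_maize, 1.0 - cfg.mix_maize - cfg.mix_parv, cfg.mix_parv]
    )
    t = np.array([cfg.t_maize, FOUNDING_AGE, cfg.t_parv])
    R = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            if a != b:
                R[a, b] = min(t[a], t[b]) * m[b]
    return m, R


def simulate_diploid_tracts(
    cfg: SimConfig,
    gmap: GeneticMap,
    n_individuals: int | None = None,
    sites_per_chrom: int = 50,
    posterior_noise: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, DiploidPosterior]:
    """Simulate diploid local-ancestry tracts and per-site posteriors.

    Each haploid genome is a Markov jump process along the genetic map (cM
    axis) with switch intensities from :func:`_transition_rates`; chromosome
    ends truncate tracts (``interior`` flags tracts not touching an end).
    Pairs of haplotypes form diploid individuals; per-site posteriors over
    the 6 unordered ancestry-pair states are indicators, optionally blurred
    toward the uniform distribution by ``posterior_noise`` in [0, 1].

    Returns ``(tracts, posteriors)``: tracts with columns individual,
    haplotype, chrom, start_bp, end_bp (0-based half-open), start_cM, end_cM,
    ancestry, interior.
    """
    cfg.validate()
    if not gmap.chromosomes:
        raise DataValidationError("empty genetic map")
    if cfg.t_maize < 1 or cfg.t_parv < 1:
        raise DataValidationError("pulse ages must be >= 1 generation")
    n_ind = cfg.n_ind_per_pop if n_individuals is None else n_individuals
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    m, R = _transition_rates(cfg)
    rate_out = R.sum(axis=1)

    tract_rows = []
    post_rows = []
    for ind in range(n_ind):
        hap_states: dict = {}
        for hap in range(2):
            for chrom in gmap.chromosomes:
                cm_start = gmap.interpolate_cM(chrom, 0.0)
                cm_end = gmap.interpolate_cM(chrom, float(gmap.chrom_lengths[chrom]))
                # initial state from the stationary distribution
                state = int(rng.choice(3, p=m))
                pos = cm_start
                segs = []
                while True:
                    if rate_out[state] <= 0:
                        segs.append((pos, cm_end, state))
                        break
                    step = rng.exponential(100.0 / rate_out[state])  # rates per Morgan, pos in cM
                    if pos + step >= cm_end:
                        segs.append((pos, cm_end, state))
                        break
                    segs.append((pos, pos + step, state))
                    pos += step
                    probs = R[state] / rate_out[state]
                    state = int(rng.choice(3, p=probs))
                hap_states[(hap, chrom)] = segs
                for k, (s_cm, e_cm, st) in enumerate(segs):
                    s_bp = int(np.floor(gmap.interpolate_bp(chrom, s_cm)))
                    e_bp = int(np.ceil(gmap.interpolate_bp(chrom, e_cm)))
                    tract_rows.append(
                        (
                            f"ind{ind:03d}",
                            hap,
                            chrom,
                            s_bp,
                            max(e_bp, s_bp + 1),
                            s_cm,
                            e_cm,
                            ANCESTRIES[st],
                            0 < k and k < len(segs) - 1,
                        )
                    )
        # per-site diploid posteriors
        for chrom in gmap.chromosomes:
            length = gmap.chrom_lengths[chrom]
            sites = np.linspace(1, length, sites_per_chrom).astype(np.int64)
            site_cm = gmap.interpolate_cM(chrom, sites.astype(float))
            states = np.empty((2, len(sites)), dtype=int)
            for hap in range(2):
                segs = hap_states[(hap, chrom)]
                ends = np.array([e for _, e, _ in segs])
                seg_state = np.array([st for _, _, st in segs])
                states[hap] = seg_state[
                    np.clip(np.searchsorted(ends, site_cm, side="left"), 0, len(segs) - 1)
                ]
            for j, pos in enumerate(sites):
                a, b = sorted((states[0, j], states[1, j]))
                pair = (
                    f"{ANCESTRIES[a]}/{ANCESTRIES[b]}"
                    if a != b
                    else f"{ANCESTRIES[a]}/{ANCESTRIES[a]}"
                )
                probs = {s: 0.0 for s in DIPLOID_STATES}
                probs[pair] = 1.0
                if posterior_noise > 0:
                    for s in DIPLOID_STATES:
                        probs[s] = (1 - posterior_noise) * probs[s] + posterior_noise / 6.0
                post_rows.append(
                    {"individual": f"ind{ind:03d}", "chrom": chrom, "pos_bp": int(pos), **probs}
                )

    tracts = pd.DataFrame(
        tract_rows,
        columns=[
            "individual", "haplotype", "chrom", "start_bp", "end_bp",
            "start_cM", "end_cM", "ancestry", "interior",
        ],
    )
    post = DiploidPosterior(pd.DataFrame(post_rows)).validate()
    return tracts, post


# ---------------------------------------------------------------------------
# Reference allele-frequency panels
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Drifted frequencies: Beta with mean p and variance F p (1-p)."""
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def simulate_reference_panels(
    cfg: SimConfig,
    n_sites: int,
    alpha_focal: float | None = None,
    fst_internal: float | None = None,
    fst_outgroup: float = 0.3,
    sample_sizes: dict | None = None,
    sampled: bool = True,
    seed: int | None = None,
) -> AlleleFreqPanel:
    """Simulate reference allele-frequency panels with known divergence.

    Sites evolve on the tree (((parviglumis, maize), mexicana), outgroup):
    an ancestral frequency is drawn per site (Uniform(0.05, 0.95)); the
    outgroup drifts by ``fst_outgroup``; mexicana drifts by ``cfg.fst_ref``;
    an internal (parviglumis, maize) node drifts by ``fst_internal``
    (default ``cfg.fst_ref``) and each of parviglumis and maize drifts a
    further ``cfg.fst_ref`` from it.  The focal admixed population ``X`` is
    the mixture ``alpha * mexicana + (1 - alpha) * maize`` (default alpha =
    the config's mean ancestry at the mean elevation).  Observed frequencies
    are binomial samples at the haploid sample sizes; ``sampled=False``
    returns the latent population frequencies instead (exact boundary cases).
    """
    cfg.validate()
    if n_sites <= 0:
        raise DataValidationError("n_sites must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    F = cfg.fst_ref
    F_int = F if fst_internal is None else fst_internal
    if alpha_focal is None:
        alpha_focal = float(np.clip(cfg.mean_ancestry().mean(), 0, 1))
    n = {"outgroup": 20, "maize": 110, "parviglumis": 100, "mexicana": 50, "focal": 20}
    if sample_sizes:
        n.update(sample_sizes)

    p_anc = rng.uniform(0.05, 0.95, n_sites)
    p_out = _balding_nichols(rng, p_anc, fst_outgroup)
    p_mex = _balding_nichols(rng, p_anc, F)
    p_int = _balding_nichols(rng, p_anc, F_int)
    p_maize = _balding_nichols(rng, p_int, F)
    p_parv = _balding_nichols(rng, p_int, F)
    p_focal = alpha_focal * p_mex + (1 - alpha_focal) * p_maize

    obs = {}
    for pop, p in (
        ("outgroup", p_out), ("maize", p_maize), ("parviglumis", p_parv),
        ("mexicana", p_mex), ("focal", p_focal),
    ):
        obs[pop] = rng.binomial(n[pop], p) / n[pop] if sampled else p

    per = np.full(cfg.n_chrom, n_sites // cfg.n_chrom)
    per[: n_sites % cfg.n_chrom] += 1
    gmap = cfg.default_map()
    frames = []
    for (chrom, length), k in zip(cfg.chrom_lengths.items(), per):
        if k == 0:
            continue
        pos = np.unique(np.sort(rng.integers(1, length, int(k))))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos_bp": pos,
            "pos_cM": gmap.interpolate_cM(chrom, pos.astype(float)),
        }))
    sites = pd.concat(frames, ignore_index=True)
    n_real = len(sites)  # may lose a few to duplicate positions
    freqs = pd.DataFrame({pop: obs[pop][:n_real] for pop in obs})
    sizes = {pop: np.full(n_real, n[pop]) for pop in obs}
    panel = AlleleFreqPanel(sites=sites, freqs=freqs, sizes=sizes,
                            meta={"alpha_focal": alpha_focal, "fst_ref": F})
    return panel.validate()


def emit_read_counts(
    panel: AlleleFreqPanel,
    coverage_mean: float,
    n_ind: int,
    seed: int,
    population: str = "focal",
) -> pd.DataFrame:
    """Low-coverage read counts: per site x individual depth and alt reads.

    Genotypes are Hardy–Weinberg draws from the site frequency, per-site
    depth is Poisson(``coverage_mean``), and the alternate-read count is
    Binomial(depth, genotype/2).  Returns a long DataFrame with columns
    site, individual, genotype, depth, alt_reads.
    """
    if coverage_mean <= 0:
        raise DataValidationError("coverage_mean must be > 0")
    rng = np.random.default_rng(seed)
    p = panel.freqs[population].to_numpy(float)
    S = len(p)
    geno = rng.binomial(2, p[:, None], size=(S, n_ind))
    depth = rng.poisson(coverage_mean, size=(S, n_ind))
    alt = rng.binomial(depth, geno / 2.0)
    site_idx, ind_idx = np.meshgrid(np.arange(S), np.arange(n_ind), indexing="ij")
    return pd.DataFrame({
        "site": site_idx.ravel(),
        "individual": ind_idx.ravel(),
        "genotype": geno.ravel(),
        "depth": depth.ravel(),
        "alt_reads": alt.ravel(),
    })
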