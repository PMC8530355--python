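"""Genome scan for selection on introgressed ancestry, end to end.

Simulates ancestry frequencies for 14 admixed populations along an
elevational cline with 40 planted mean-shift outliers and 30 planted steep
clines, fits the MVN null (mean vector alpha, covariance K) to the data,
simulates 100k unlinked null loci, and runs both one-tailed scans at a 5%
FDR.  Prints how many planted loci each scan recovers.
"""

import numpy as np

import admixscan as ax

cfg = ax.SimConfig(n_loci=10_000, n_outlier_loci=40, n_clinal_loci=30, seed=0)
mat, truth = ax.simulate_ancestry_frequencies(cfg)
meta = [ax.PopulationSample(p, "maize", e)
        for p, e in zip(cfg.pop_ids, cfg.elevations_km)]

cov = ax.estimate_K(mat)
null = ax.simulate_null(cov, n_sim=100_000, seed=1)
print(f"mean ancestry range across populations: "
      f"{cov.alpha.min():.3f}-{cov.alpha.max():.3f}")
print(f"null model: {null.sims.shape[0]} simulated loci, "
      f"truncated fraction {null.truncated_fraction:.2e}")

mean_res = ax.mean_ancestry_scan(mat, null, chrom_lengths=cfg.chrom_lengths)
slope_res = ax.slope_scan(mat, meta, null, chrom_lengths=cfg.chrom_lengths)

up = mean_res.table["reject_upper_q0.05"].to_numpy()
lo = mean_res.table["reject_lower_q0.05"].to_numpy()
steep = slope_res.table["reject_upper_q0.05"].to_numpy()
is_high = (truth["planted_class"] == "high_mean").to_numpy()
is_low = (truth["planted_class"] == "low_mean").to_numpy()
is_steep = (truth["planted_class"] == "steep_slope").to_numpy()

print(f"mean-ancestry scan: {up.sum()} high outliers "
      f"({up[is_high].sum()}/{is_high.sum()} planted high-mean loci found), "
      f"{lo.sum()} deficits ({lo[is_low].sum()}/{is_low.sum()} planted)")
print(f"slope scan: {steep.sum()} steep-cline outliers "
      f"({steep[is_steep].sum()}/{is_steep.sum()} planted clines found)")
print(f"outlier intervals derived: {len(mean_res.outliers)} "
      f"(merged contiguous loci, halfway-extension rule)")
thr = slope_res.thresholds[("upper", 0.05)]
print(f"slope at the 5% FDR decision boundary: {thr:.3f} per km")
print("-> planted signals are recovered; false discoveries are rare because")
print("   the null preserves the ancestry covariance between populations.")
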