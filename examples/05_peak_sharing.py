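"""How often do populations share high-introgression peaks by chance?

Calls per-population introgression peaks (> mean + 2 s.d.), measures the
fraction of loci in peaks shared by each population pair, and compares the
observed sharing against the MVN null: simulated unlinked loci classified by
the same empirical thresholds, with a 95% percentile band.  Excess sharing
beyond the band is what points to parallel adaptive introgression rather
than shared drift.
"""

import numpy as np

import admixscan as ax

cfg = ax.SimConfig(n_loci=8000, K_shared=0.5, seed=8)
mat, _ = ax.simulate_ancestry_frequencies(cfg)

pk = ax.call_peaks(mat, sd_mult=2.0)
print(f"peak thresholds span {pk.thresholds.min():.3f}-{pk.thresholds.max():.3f}")
obs = ax.sharing(pk.flags, combos_max=3)

cov = ax.estimate_K(mat)
null = ax.null_sharing(cov, pk.thresholds, n_sim=50_000, seed=9,
                       n_obs_loci=cfg.n_loci, combos_max=3)

obs_pairs = {tuple(r["combo"]): r["fraction"]
             for _, r in obs.pair_frame().iterrows()}
inside = 0
pairs = null.pair_frame()
for _, row in pairs.iterrows():
    f = obs_pairs[tuple(row["combo"])]
    inside += row["band_low"] <= f <= row["band_high"]
print(f"{inside}/{len(pairs)} population pairs have observed sharing inside "
      f"the null 95% band")
top = obs.observed_sets.head(3)
print("most common shared peak sets (population set: % of loci):")
for _, r in top.iterrows():
    print(f"  {'+'.join(r['set'])}: {100 * r['fraction']:.2f}%")
print("-> here the data were generated under the null, so sharing stays")
print("   inside the band; selection would push pairs above it.")
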