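# Methods

`admixscan` analyses local-ancestry frequencies in sympatric admixed
populations sampled along an environmental gradient — the motivating system
is highland Mexican maize growing beside its wild teosinte relative
*Zea mays* ssp. *mexicana* — and asks where selection has favoured or
removed introgressed ancestry. This note documents the models, the
estimators, the synthetic-data generator, and the numerical choices, in
enough detail to reproduce every number the package computes.

## The MVN null model

For `P` admixed populations, the introgressed-ancestry frequency at locus
`l` in population `i`, `Anc_{i,l}`, fluctuates around the population's
genomewide mean through drift and shared post-admixture history. The null
model keeps exactly those two moments:

- `alpha_i = (1/L) Σ_l Anc_{i,l}`, the genomewide mean per population, and
- `K[i,j] = (1/L) Σ_l (Anc_{i,l} − alpha_i)(Anc_{j,l} − alpha_j)`,

with the population (`1/L`) normalizer, not the sample one. Diagonal
entries capture within-population variance in local ancestry across the
genome; off-diagonals capture the covariance created by shared gene flow
and drift — at loci where one population carries excess introgression,
populations with shared history tend to as well, which is why naive
per-population outlier tests overstate independence.

Null loci are simulated as independent draws from `MVN(alpha, K)` and then
clamped to `[0, 1]` (truncation by clamping, not rejection; the clamped
fraction is recorded and is ~1e-4 under default conditions, so the moment
distortion is negligible). If the Cholesky factorization of `K` fails, a
jitter `eps·I` escalates from 1e-12 to 1e-8 before giving up; every jitter
is logged.

### Scans and FDR calibration

Two per-locus statistics are computed identically on observed and simulated
loci:

- **mean-ancestry scan** — the unweighted mean frequency across
  populations; the upper tail flags candidate adaptive introgression, the
  lower tail flags deficits;
- **slope scan** — the OLS slope (per km) of population ancestry frequency
  on elevation, intercept included, populations weighted equally (the
  regression is at population level because the null simulates populations,
  not individuals).

Observed statistics become pseudocount empirical p-values,
`p = (1 + #{null ≥ obs}) / (1 + n_sim)` for the upper tail (mirrored for
the lower), so p is never zero and remains valid for finite simulations;
ties count toward the tail. Upper and lower tails form two separate
one-tailed families, each Benjamini–Hochberg-corrected; decisions are
reported at q ∈ {0.01, 0.05, 0.10}, with every locus entering BH (a thinned
variant is the caller's choice — pass a thinned matrix). The statistic
value at the decision boundary (the least extreme rejected value) is
reported so a threshold line can be drawn over a genome scan.

One consequence of the pseudocount floor worth knowing: with
`n_sim = 100,000` null draws and 10,000 loci, the smallest attainable
p-value (1/100,001) sits just above the BH step-up bound for a single
rejection (0.05/10,000), so on *pure null* data the scans reject
essentially nothing — conservative self-calibration, verified by the
acceptance tests.

Outlier and desert intervals are derived from contiguous qualifying loci:
each locus spans halfway to its neighbours (chromosome ends clip), adjacent
qualifying loci merge. Deserts are rank-defined: the
`floor(quantile · L)` loci with the lowest cross-population mean ancestry,
ties broken by genome order, so the desert set never exceeds the nominal
fraction.

## Peak calling and sharing

A population's introgression peaks are loci strictly above
`mean + 2 s.d.`, with the s.d. computed over loci using the same `1/L`
normalizer as `K`'s diagonal, so the peak threshold and the null covariance
describe the same dispersion (the choice of normalizer is undocumented in
the field's informal usage; consistency with `K` decides it here). Sharing
for a set of populations is the fraction of *all genomewide loci* flagged
in every member (a documented alternative denominator — the union of peaks
— is easy to compute from the returned flags but is not the default).
Combinations are enumerated to `combos_max` (default 5) and, separately,
the exact observed flagged sets are ranked by frequency, which avoids the
2^P blowup while still exposing the large high-elevation sharing sets.

The sharing null classifies MVN draws by the *empirical* thresholds and
computes sharing identically; its 95% band per combination comes from
resampling `n_obs_loci` loci (the observed-data size, so the band reflects
the sampling noise an empirical fraction actually has) from the simulated
pool.

## Population-genetic estimators

- **Hudson FST** with the finite-sample corrections,
  `num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `den = p1(1−p2) + p2(1−p1)`, combined across sites as a ratio of
  averages (not an average of ratios). Sites monomorphic for the same
  allele in both populations are 0/0 and excluded from both sums; if none
  remain the statistic is undefined and raised, never silently NaN.
- **PBS** `= (T12 + T13 − T23)/2` with `T = −log(1 − FST)`; negative
  values are legitimate and returned as-is; `FST = 1` (infinite branch) is
  rejected.
- **f4(A,B;C,D)** `= mean_l (pA−pB)(pC−pD)`, the negative ABBA-BABA
  numerator per site; per-block means over 1 cM map windows are retained.
- **f4-ratio admixture proportion**
  `alpha = f4(outgroup, parviglumis; X, maize) / f4(outgroup, parviglumis;
  mexicana, maize)`: the denominator measures the internal branch
  separating the (maize, parviglumis) pair from mexicana, and the ratio is
  the fraction of that branch shared by the focal population X, i.e. X's
  mexicana ancestry proportion. The CI is a percentile block bootstrap
  (default 500 replicates) resampling the same 1 cM blocks jointly for
  numerator and denominator. A denominator within `denom_tol` of zero is an
  error carrying the denominator value. Jackknife Z-scores are deliberately
  not provided — the block bootstrap is the one interval method here.
- **pi** per site is the unbiased `2p(1−p)·n/(n−1)`; within-ancestry
  diversity and FST are meant to be computed on frequencies within called
  homozygous-ancestry tracts (posterior > 0.8, strict) — a deliberate
  frequency-based route rather than genotype-likelihood SFS machinery,
  which belongs to external tools; the FST parameterization is the same
  Hudson form those tools report.
- **Site filters** keep `MAF ≥ 0.05`, `≥ 150` individuals with data, and
  total depth not *exceeding* 2.5× the sample mean (a site exactly at the
  cutoff is kept; every comparison in the package is strict exactly where
  the rule says "exceeds"/">" and inclusive where it says "≥").
- **AIM ascertainment** computes per-site PBS three ways (each reference
  taxon focal), keeps sites in the top decile of any configuration
  (nearest-rank quantile, ties kept), then thins by a greedy walk in cM
  order keeping a site only if ≥ 0.001 cM beyond the last kept site —
  first-come, deterministic, ties broken by bp.

## Genetic map handling and windows

Raw lifted-over marker tables are cleaned in order: markers assigned to the
wrong chromosome are dropped; markers on a caller-supplied exclusion list
(complex rearrangements that need manual curation) are dropped; within each
chromosome the longest strictly-increasing cM subsequence is retained,
which removes the minimal number of out-of-order markers. Among equally
minimal solutions the earliest markers are kept, so a later order-breaking
marker is the one dropped — deterministic and stable in map order. Terminal
recombination rates extend to the chromosome ends, so bp↔cM interpolation
(piecewise linear, exact at markers, strictly monotone) is defined
everywhere on the chromosome.

Windows are successive 1 cM slices; the final sub-1 cM window is kept and
flagged `partial`. Each carries its recombination rate (cM span / Mbp
span), coding-bp overlap with merged CDS intervals, and the mean ancestry
of loci assigned by bp position (half-open windows; a boundary locus
belongs to the right window). Quintiles sort windows by the metric and cut
at cumulative physical-bp fifths, so each quintile covers ~1/5 of the
genome within one window's length.

Quintile-level Spearman's rho has only 5 points, so its CI comes entirely
from the bootstrap (windows resampled within quintiles); replicates with
tied quintile means are retained with average ranks rather than dropped.
Window-level rho with a genomewide window bootstrap is the
higher-resolution companion.

## Enrichment tests

Candidate genes are padded ±20 kb (clipped to chromosome bounds). Overlap
is half-open-interval intersection with ≥1 shared bp; a gene counts once
regardless of how many target intervals it touches. The permutation null
re-places every gene uniformly on its own chromosome, preserving length and
allowing overlaps among shuffled genes (the standard BED-shuffle default;
whether placement should be cross-chromosome is genuinely open — within-
chromosome preserves chromosome-level composition and is used here).
P-values are pseudocounted and one-tailed in both directions; ties count
toward both tails, so `p_greater + p_less ≥ 1 + 1/(1+n_perm)`.

## The synthetic-data generator

The generator emulates the target study design so every stage is testable
without field data: 14 sympatric populations along a 1.547–2.600 km
elevational gradient, mean introgressed ancestry
`alpha_base + beta_elev · elevation` with defaults `−0.20 + 0.22/km`
(mean ancestry 0.14–0.37 across the gradient, matching a crop receiving
~20% wild ancestry on average with a strong cline), drift covariance
`K = K_scale · [(1−K_shared)·I + K_shared·11']` with `K_scale = 0.0025`
(per-population ancestry s.d. 0.05 across loci) and `K_shared = 0.3`
(a third of the variance shared between populations) — two parameters that
give a controllable, always-PSD covariance. Admixture pulses default to
1014 (maize) and 173 (parviglumis) generations with mixing proportions
0.75/0.05 into a mexicana founding background, and sequencing coverage
defaults to 1×.

Frequencies are Gaussian-then-truncated, matching the null model's own
convention, rather than logit-normal; the truncated fraction is recorded on
the returned matrix so tests can bound the induced bias (< 1% truncation
keeps the K-recovery error inside 5% Frobenius). Planted signal loci
perturb the mean: mean-shift outliers move all populations by ±0.15;
clinal loci add `0.8/km · (elev − mean elev)`, steepening the cline without
moving the locus mean. Truth records carry each locus's class and true mean
vector for parameter-recovery tests. An empirical-resample mode draws loci
with replacement from a supplied matrix instead, for users who prefer to
preserve the empirical marginal distribution over the parametric (alpha, K)
summary; the parametric mode is the default.

Haploid tracts follow a reversible Markov jump process along the cM axis
with switch rate from ancestry `a` to `b` of `min(t_a, t_b) · m_b` per
Morgan — recombination since the more recent of the two pulses can swap
local ancestry, landing in `b` with probability equal to `b`'s genomewide
proportion. This is the same single-pulse-per-ancestry approximation the
forward model of read-count ancestry HMMs makes; its stationary
distribution is exactly the mixing proportions, and interior sojourn
lengths are exponential with mean `100/(rate out)` cM, which is what the
tract-length consistency checks assert. Chromosome ends censor tracts, so
only interior tracts enter length statistics. Diploid posteriors over the 6
unordered ancestry-pair states are indicators, optionally blurred toward
uniform by a noise parameter.

Reference panels evolve by Balding–Nichols drift (Beta with mean `p` and
variance `F·p(1−p)`) on the tree
`(((parviglumis, maize), mexicana), outgroup)`: the ancestral frequency is
Uniform(0.05, 0.95); mexicana and each of maize/parviglumis drift by
`fst_ref` (default 0.1); the internal (maize, parviglumis) node drifts by
`fst_internal` (default also `fst_ref` — the internal branch is what the
f4-ratio denominator measures, and a branch of the same order as the
terminal drift gives the estimator its working precision at 1e5 sites); the
outgroup by 0.3. Under this scheme the Hudson estimator between two
sister panels recovers `fst_ref` exactly in expectation because the
finite-sample corrections remove the binomial sampling variance. The focal
population is the deterministic mixture `alpha·p_mex + (1−alpha)·p_maize`,
so the f4-ratio has expectation exactly `alpha`. Read counts are
Hardy–Weinberg genotypes, Poisson depth, binomial alternate reads — a flat
model with no sequencing-error or mapping-bias structure.

What the generator does **not** emulate: linkage between loci (the null is
unlinked by construction, as is the model it calibrates), recombination
hotspots, linked selection outside planted loci, ongoing migration (a
single pulse per ancestry), sequencing error, or reference bias. Passing
tests therefore show the estimators and calibration machinery are correct
under the stated model, not that the model captures every feature of field
data.

## Problem sizes and determinism

Acceptance-level checks run at: 20 replicates of L = 10,000 loci x 14
populations against 100,000 null draws (scan self-calibration); 50
replicates of 100,000-site panels (f4-ratio CI coverage); 100,000 loci
(K recovery); 200 haplotypes on a 100 cM chromosome (tract lengths); 20
replicates of 5,000-locus sharing comparisons against 20,000 classified
null draws; 100 shuffle-test replicates at 300 permutations. These sizes
make every stochastic check reproducible in well under a minute or two each
while leaving Monte-Carlo error far inside the asserted tolerances.

Every generator and every resampling routine is a pure function of its
(config, seed) arguments via `numpy.random.default_rng`; nothing reads
global random state.

## Known limitations

- The MVN null treats loci as exchangeable and unlinked; spatially
  autocorrelated nulls (HMM or windowed) are out of scope.
- Per-locus slope regressions are population-level and unweighted; there is
  no sample-size weighting or individual-level regression, and no covariate
  other than elevation.
- The f4 machinery works from population allele frequencies; a
  single-read-per-individual resampling mode for very low coverage is not
  implemented — `emit_read_counts` provides the raw material if needed.
- Tract simulation approximates a two-pulse history with pairwise
  most-recent-pulse switch rates; it is a generator for testing inference
  machinery, not a coalescent simulation.
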