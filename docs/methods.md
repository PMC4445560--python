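# Methods

## Demographic model

The simulator implements a two-deme serial coalescent for haploid mtDNA.
All population sizes are female effective sizes and a pair of lineages in a
deme of size N coalesces at instantaneous rate 1/N. Time runs backwards in
generations BP with a 6-year generation interval; the present is fixed at
2000 CE so that 8,500 BCE corresponds to 1,750 generations BP and 6,400 BCE
to 1,400 generations BP (both constants are configurable).

Fixed constants: ancestral aurochs size N_anc = 45,000 (for
t >= T_dom = 1,750); modern Near Eastern size N_NE = 1,007,170; modern
European size N_E = 7,942,392; migration-epoch change at 5,000 BCE
(7000/6 generations BP, kept as an exact rational); mutation rate 45% per
site per Myr. Free parameters: bottleneck size N_D, founding proportion P,
early and late migration rates M_E, M_L.

Design choices that were genuinely open:

* **Europe's founding size** is P x (NE size at the split), and the NE
  deme's own trajectory is *not* reduced at the split. Deme trajectories
  are specified independently, as in serial-simulation conventions for
  this kind of model; this is an assumption, not a statement about any
  particular prior implementation.
* **Migration is symmetric**, with the same per-lineage rate in both demes;
  the model statement gives a single rate per epoch without direction.
* **Mutation** is finite-sites with a uniform rate and uniform choice of
  target base (no transition bias, no rate heterogeneity): each hit picks a
  uniform site and changes the base to a uniform different base. The rate
  is interpreted per site: 0.45e-6 /site/year x 6 years = 2.7e-6
  /site/generation. With 240 bp and deep (ancestral-pool) branches this
  produces visible recurrent-hit saturation, which is part of the model.
* **Time integration.** Exponential-size epochs are handled by closed-form
  inversion of the cumulative coalescent hazard (no discretization). Epoch
  boundaries, sampling times and migration-rate changes truncate each
  waiting-time draw; redrawing after a boundary is exact by memorylessness.
  The simulator is validated against closed forms (E[TMRCA] = N,
  E[pair length] = 2N + t for serial pairs, E[pi] = 2N mu) and against
  msprime on a two-epoch model (Kolmogorov-Smirnov on S and pi).

## Summary statistics

The ABC vector has 32 entries: for each of the four sample groups
(ancient Near East/Anatolia, ancient Europe, modern Near East/Anatolia,
modern Europe, in that fixed order) the number of haplotypes K, Nei's
unbiased haplotype diversity Ĥ, mean pairwise differences pi, segregating
sites S and Tajima's D; for each of the six ordered group pairs
(lexicographic in the fixed order) the AMOVA-based Phi_ST and the mean
between-group pairwise differences. The choice of the five within- and two
between-group statistics is configurable and echoed in output metadata.

Missing data (N, -, ?) is handled by pairwise deletion for pi, S and
F_ST. Haplotype calling defaults to a wildcard policy — two sequences share
a haplotype iff they agree wherever both are non-missing, with clusters
merged transitively (order-independent by construction); a complete-sites
policy (drop any column containing missing data, then exact identity) is
available. Undefined Tajima's D (S = 0, or n = 2 where the variance
estimator vanishes) is encoded as 0 with a flag; simulated and observed
vectors are treated identically so the encoding cannot bias rejection.

Tajima's D and Fu's Fs p-values are simulation-based: the null is a
constant-size neutral coalescent at theta = pi-hat (10,000 samples by
default in the CLI report; configurable), lower tail,
p = Pr(stat_sim <= stat_obs). Fu's S' = Pr(K >= k_obs) is computed exactly
from the Ewens sampling formula via log-space unsigned Stirling numbers of
the first kind, with theta = pi-hat. The standard deviation reported for pi
uses Tajima's (1983) total variance for a non-recombining locus; Nei's
sampling variance is used for Ĥ.

Two F_ST estimators are exposed: `phi_st` (default), the two-group AMOVA
variance-component ratio on pairwise sequence differences, and
`haplotype_freq`, a frequency-based Weir-Cockerham/Reynolds-style
estimator on haplotype counts. Permutation p-values shuffle individuals
between the two groups with sizes preserved; p is the plain proportion of
permutations with F_ST >= observed. Negative estimates are reported as
computed and clamped to 1e-6 only for ordination.

## ABC

Plain rejection: every statistic is standardized by its standard deviation
across the whole simulation table (MAD available as an option), constant
columns are dropped and logged, distance is Euclidean, and the
ceil(tolerance x n) closest rows are retained with ties broken by row
index. No post-rejection regression adjustment is applied. Per-row seeds
derive from the master seed as SeedSequence(master, spawn_key=(row,)), so
batches are reproducible regardless of execution order.

Posterior summaries use Gaussian KDEs with Silverman bandwidths reflected
at the prior bounds (bounded uniform priors put modes at or near bounds,
e.g. for M_L, and reflection prevents smearing mass outward). Marginal
modes are grid argmaxes (512 points); the joint (N_D, P) density is a
256 x 256 histogram smoothed with a Gaussian filter in reflect mode, which
realizes a product-kernel boundary-reflected KDE at negligible cost.
Credible intervals are highest-posterior-density intervals, computed as
the narrowest grid window holding the target mass (equal to the HPD set
for unimodal densities; chosen over equal-tailed intervals because
boundary-mode posteriors make equal tails misleading). Parameter
correlations among accepted sets are Pearson r with two-sided permutation
p-values using the (1+k)/(1+N) estimator.

## Spatial analyses

Geographic distances are haversine great-circle distances (R = 6,371 km)
between group centroids; centroids are planar means of site coordinates,
which matches the precision of "centre of the sites/country" placements —
no spherical-mean refinement is warranted, and this approximation is noted
wherever Mantel results are compared against external values. The Mantel
statistic is the Pearson correlation of upper-triangle entries, with
one-sided permutation p = (1 + k)/(1 + N) under joint row/column
permutation of one matrix. Ordination is Kruskal non-metric MDS
(stress-1), best of 20 random restarts, negative F_ST entries clamped to
1e-6 for the ordination only (count reported); classical metric scaling
is available through the underlying backend if needed.

## Synthetic data

The generator emulates the study layout: 13 ancient spatiotemporal groups
(24 Near Eastern/Anatolian + 169 European sequences) with per-group period
bounds spanning 7,000-1,400 BCE, and modern country groups (100 Near
Eastern/Anatolian + 497 European), 790 sequences of 240 bp in total, all
scalable by a single factor (minimum two sequences per group). Sample ages
are drawn uniformly within each group's period bounds and each ancient
sample enters the genealogy at its own age (a group-midpoint policy is
available); site coordinates are drawn uniformly within per-region bounding
boxes. True parameters are written to a sidecar JSON, separate from the
metadata the pipeline reads.

What the generator does *not* emulate: real haplogroup motif structure
(T3/Q/T2/P), sequencing/damage error, alignment gaps or missing-data
patterns, and non-uniform age distributions within periods. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the assumed model, not robustness to those real-data features.

## Validation scale and numerical choices

The bundled "desk" profile scales group sizes by 0.1 (79 sequences), uses
20,000 simulations and a 1% rejection tolerance; the parameter-recovery
experiment shares one reference table across ten pseudo-observed datasets
generated at (N_D = 100, P = 0.7, M_E = 0.002, M_L = 0.0001). At this
scale a single repetition's posterior mode is noisy, so the recovery check
evaluates HPD coverage per repetition and the median of the ten modes
against truth. The "full" profile (5,000,000 simulations, tolerance
0.1%, unscaled sample sizes) reproduces the complete study configuration and is
practical only as a long batch run.

Degenerate inputs: monomorphic alignments give Ĥ = 0 and undefined
D/Fs (rendered "-"); a KDE over identical values returns a point mass and
zero-width intervals; an all-zero distance matrix is rejected for
ordination. Sensitivity multipliers on N_NE and N_E (e.g. 10 or 0.1) are
plain model fields, so order-of-magnitude robustness runs are
configuration, not code changes.

## Known limitations

* No recombination (appropriate for mtDNA), at most two demes, no
  selection, no haplogroup nomenclature assignment.
* The frequency-based F_ST estimator is an ANOVA on haplotype indicators,
  not the exact historical Reynolds-Weir-Cockerham implementation of any
  particular toolchain; the two estimators can differ on real data.
* Exact per-sample ages of real ancient datasets are interval-censored;
  the midpoint convention is a modelling choice exposed as configuration.
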