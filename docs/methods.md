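# Methods

This note documents the statistical models, estimators, numerical
choices, and known limitations of `pinegraph`, in the order data flow
through the package.

## Genotype model and encodings

Genotypes are diploid, co-dominant calls with opaque string allele
codes; microsatellite fragment lengths are identifiers only (all SSR
analyses are infinite-alleles analyses and need identity, not size).
Missing data is the literal token `NA`; any other malformed token is an
error, because silently treating typos as missing loses data.  SNP
panels are filtered once over the pooled dataset (call rate > 0.80,
pooled minor-allele frequency > 0.01), mirroring how such panels are
assembled in practice.

For multivariate analyses each individual is encoded as a concatenated
per-locus allele-dosage vector, one coordinate per (locus, allele) with
value count/2 ∈ {0, 0.5, 1}.  Missing calls are imputed with the
population-mean dosage so every individual has a complete vector; with
the call-rate filters in place this perturbs centroids negligibly.  The
encoding sits behind `popgraph.encode_individuals` so alternatives
(e.g. one-hot) can be swapped in.

## Diversity and differentiation

Per population × locus: H_E = 1 − Σp² (Nei's 1978 small-sample variant
`2n/(2n−1)·H_E` behind `unbiased=True`, because the conventions of
legacy software differ), A_E = 1/Σp², H_O the observed heterozygote
fraction, F_IS = 1 − H_O/H_E (undefined when H_E = 0).  Multilocus
population values are unweighted means across loci; multilocus F_IS is
the ratio of mean heterozygosities (ratio-of-means), not a mean of
ratios, so nearly-monomorphic loci cannot dominate.  Confidence
intervals for range-wide means are percentile bootstrap over
populations (default 10,000 draws); geographic trends use Pearson r with
permutation of population identifiers and the (1+c)/(n+1) p-value
convention used everywhere in the package.

F_ST is Weir & Cockerham's θ: per-allele variance components a (among
populations), b (between individuals within), c (within individuals),
summed over alleles and loci, with θ = Σa/Σ(a+b+c) — a ratio of sums,
never a mean of per-locus ratios.  CIs are percentile bootstrap over
loci on the summed-component ratio.  G′_ST uses Nei & Chesser's
sample-corrected H_S and H_T, standardized per Hedrick; the multilocus
value standardizes the across-locus means of H_S and H_T.  Hierarchical
F-statistics place a grouping level (e.g. climate groups) above
populations: unbalanced nested ANOVA moment estimators on gene-copy
allele indicators, components summed over alleles and loci; negative
components are reported as-is (effectively zero).  The headline group
fraction is σ²_CG/(σ²_CG + σ²_POP).

Pairwise LD uses the standard two-locus EM for haplotype frequencies
from unphased diploids (initialized at linkage equilibrium, 100
iterations or Δloglik < 1e-10; only double heterozygotes are
phase-ambiguous), pooled across populations by default; r² = D²/ΠpAq
and |D′| = |D|/D_max.  Locus pairs sharing a gene/contig label are
classed intragenic.

## Population Graphs and cGD

The Population Graph is a Gaussian-graphical-model summary of
among-population covariance.  Squared Euclidean distances between
population centroid vectors are Gower double-centered into the
among-population covariance C; the precision matrix is the
pseudo-inverse (tolerance 1e-12 — the centering makes C exactly rank
k−1, so a pseudo-inverse is the expected path, not an exception);
partial correlations ρᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ); an edge is retained when the
edge-exclusion deviance −N·ln(1−ρ²ᵢⱼ) exceeds χ²₁(α), with N the total
individual count and α = 0.05.  Edge length is the centroid distance
√(Cᵢᵢ+Cⱼⱼ−2Cᵢⱼ); cGD is all-pairs Dijkstra over edge lengths.

Two deliberate choices deserve emphasis:

* **Sampling-noise correction (default).**  Squared distances between
  *sample* centroids overestimate the true centroid distances by the
  variance of each mean (s²ᵢ/(nᵢ−1) + s²ⱼ/(nⱼ−1), with s² the unbiased
  total within-population variance).  `estimate_population_graph`
  subtracts this before centering (`noise_corrected=True`).  For
  low-information panels (tens of biallelic loci, ~10 diploids per
  population) the noise term is comparable to the structure signal, and
  the correction measurably stabilizes the estimated topology: in the
  stepping-stone experiments the cGD self-congruence of independent SNP
  replicates rises from ~0.57 to ~0.67.  The uncorrected spec-form
  covariance remains available (`among_population_covariance`,
  `noise_corrected=False`).
* **Calibration of the edge test.**  Centering leaves a structural
  offset: under exchangeable noise the pseudo-inverse partial
  correlations concentrate at 1/(k−1) rather than 0 (because
  pinv(I − J/k) = I − J/k), so the χ²₁ edge test is anticonservative at
  nominal α — a property of the methodology, not of this
  implementation.  Restoring the sampling-noise variance on the
  diagonal does yield a ~5% false-edge rate under independence, but it
  also floods structured data with spurious negative long-range partial
  correlations and collapses the simulation experiments, so it is not
  used.  The test suite pins the actual null behaviour instead.

Disconnected graphs are legal objects but illegal inputs to congruence
and cGD-based regression: disjunct components produce undefined cGD
values, and such replicates are discarded in the experiments (the
discard is audited).  Congruence is a one-tailed (greater) Mantel test —
the hypothesis is that two topologies share *more* structure than
chance.  The consensus graph is the edge intersection with averaged
lengths.

## Environmental association

Single-locus: focal-allele (pooled-minor, alphabetical tie-break)
frequencies are arcsin√p transformed; loci are residualized by OLS on
trend-surface predictors (the 9 centered monomials of longitude/latitude
to total degree 3, or the linear pair, or nothing); residuals are
rank-correlated with the leading climate PCs (eigenvalue > 1 rule);
two-sided p from the t approximation t = ρ√((n−2)/(1−ρ²)); step-up
(BH-derived) q-values with q < 0.05 as the screen.  Results are
invariant in |ρ| to the focal-allele choice.

Multilocus: the response matrix is arcsin√p per allele per locus (SSRs)
or per locus (SNPs).  RDA is the eigen-decomposition of the OLS
projection of centered Y on centered X; R² = constrained/total inertia;
R²_adj is Ezekiel's correction, and conditional (partial) adjusted R²
comes from differences of nested unconditional fits, which makes the
decomposition additive by construction.  Partial RDA residualizes both
Y and X on the conditioning set.  Significance is permutation ANOVA on
the pseudo-F (raw-Y row permutation for unconditional models, reduced-
model residual permutation for conditional ones).  Stepwise geographic
selection is forward-backward with marginal permutation tests
(p_in = 0.05, p_out = 0.10, 199 permutations — conventional defaults,
all configurable and logged in the audit trail).  Variance partitioning
reports climate-independent, geography-independent and confounded
fractions of the joint R² (raw, not adjusted); the confounded fraction
may be negative and is reported as such.

MRM regresses the vectorized lower triangle of the response distance
matrix on predictor distance matrices, with significance from joint
row/column permutation of the response.  With one predictor, MRM R²
equals the squared Mantel r — asserted as a cross-module consistency
check.  Conditional MRM residualizes the vectorized response on the
conditioning distances, reassembles a (possibly negative-valued)
symmetric residual matrix and reruns MRM; predictors are not
residualized by default.

## The simulation engine

The generator encodes the study conditions of the marker-comparison
experiments: a 1-D chain of 10 demes; a global effective size of 10,000
diploids split evenly across demes (per-deme 1,000 — the reading
consistent with the observed SSR heterozygosity ≈ 0.74, since per-locus
θ = 4N_deme·μ = 4 gives equilibrium H = θ/(1+θ) = 0.8, whereas per-deme
10,000 gives θ = 40, H ≈ 0.98 and no recoverable structure;
`size_is_per_deme=True` restores the other reading); adjacent-deme
scaled migration 2N_em = 2.5 in its conventional per-deme meaning; 10
diploids sampled per deme.  Ancestries come from msprime's structured
coalescent.

SNP loci (44) are simulated conditional on exactly one segregating site
(fixed-S): with μ = 10⁻⁹ per site the unconditioned per-locus θ ≈ 4×10⁻⁵
yields essentially no polymorphism, and conditioning on one site, placed
on a branch with probability proportional to branch length, is the only
construction that delivers a fixed-size biallelic panel with the neutral
site-frequency spectrum.  SSR loci (12) follow the infinite-alleles
model: Poisson mutations on branches (msprime's InfiniteAlleles model at
rate μ, default 10⁻³), each creating a globally novel allele; a gene
copy carries its most recent mutation.  The IAM equilibrium
H = θ/(1+θ) is verified against Ewens' closed form in the suite.

Simulated climate is 19 mutually independent variables, each a linear
gradient along the chain plus unit Gaussian noise.  The shared slope is
calibrated by Monte-Carlo lookup (10⁴ fixed-noise draws, bisection) so
that the **expected Mantel correlation between the Euclidean distance
over the standardized 19-variable set and the deme lattice distance
equals the requested true r**.  Calibrating each variable separately to
the target instead lets the 19-fold combination amplify the joint
correlation far past the target (measured ≈ 0.86 for a per-variable
0.40), which contradicts the small overestimation the experiments are
supposed to exhibit; the joint definition is also the only scale on
which "bias of the estimated Mantel r relative to true r" is a coherent
quantity.  true r = 0 means pure noise.  The calibration is cached per
(demes, variables, r) and fails fast outside [0, 0.95].

The two experiments run per-replicate independent genealogies for both
panels, estimate both Population Graphs at α = 0.05, discard replicates
where either graph is disconnected or empty (abort if more than half
are discarded), and record Mantel statistics only (no per-replicate
permutation tests are needed for the summaries).  Summaries include
means, SDs, 2.5/97.5 percentiles, the discard audit, a config echo, and
the empirical quantile of a user-supplied observed value under the
(1+c)/(n+1) convention.

What the generator does *not* emulate: linkage between loci,
recombination within loci, selection, stepwise microsatellite mutation,
range expansion or bottlenecks, and spatially autocorrelated mutation
rates.  Passing experiments therefore show that the analysis stack
behaves correctly under a neutral equilibrium null — not that real data
meet those assumptions.

Observed behaviour at 1000 replicates (seeds as in
`scripts/acceptance.py` and the test suite): under independent climate
the per-marker mean cGD–climate Mantel r is ≈ 0.01 (|r| < 0.05) and the
SNP−SSR difference is centered on zero; at true r = 0.40 the SSR mean
is ≈ 0.40 and the SNP mean ≈ 0.30–0.31 (bias ≈ 0.10): the SSR graphs
recover the chain almost exactly while the 44-SNP graphs are noisier,
attenuating the correlation.  A noisy structure estimate cannot
*over*-shoot a truth defined against the latent lattice, so mild
underestimation on the SNP side is the expected behaviour of this
construction.  Marker-type congruence averages ≈ 0.80 (95% interval
≈ 0.57–0.94), and an observed between-marker congruence of 0.132 falls
below every simulated replicate (empirical quantile < 0.01).

## Determinism and seeds

Every stochastic operation takes a seed and uses a single
`numpy.random.Generator`; experiments derive per-replicate child seeds
from the master seed, and the CLI derives per-stage seeds by hashing
(seed, stage).  Reruns with the same config and seed are byte-identical;
msprime seeds are constrained to [1, 2³¹).

## Problem sizes

The test suite runs the experiments at 150 replicates and the acceptance
script at 1000 (configurable via `--n-reps`); at 150 replicates the
Monte-Carlo standard error of the experiment means (~0.01) is an order
of magnitude below the tolerances asserted against them.
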