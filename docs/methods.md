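# Methods

This note documents the models and numerical choices behind `corridorgen`,
the assumptions the synthetic data make, and what the test suite does and
does not demonstrate about real data.

## Genotype model and QC

Genotypes are unordered diploid allele pairs over integer allele codes
(the convention of Genepop files); pairs are stored sorted so comparisons
are canonical, and a half-missing call is treated as fully missing.

**Replicate consensus.** Non-invasive genotyping repeats each locus
amplification (four replicates by default). The consensus call at a locus
is the modal diploid call, with the multiple-tubes rule that a heterozygote
is accepted only when observed in ≥ 2 replicates — a single heterozygous
observation among homozygous replicates is more plausibly a false allele
than a real heterozygote. Per-locus quality is the fraction of non-missing
replicates matching the consensus; the sample quality index (QI) is the
mean over loci with a consensus (all-missing loci are excluded from the
denominator — the index measures agreement, not completeness). Samples are
retained when QI ≥ 0.75 and ≥ 12 loci are typed. With four replicates the
0.75 cutoff is exactly the "3 of 4 agree" boundary.

**Unique individuals.** Two samples are the same individual when they
overlap at ≥ 12 typed loci and mismatch at ≤ `max_mismatch` of them
(default 0; exposed because non-invasive pipelines often allow 1–2).
Matching is closed transitively; the representative is the
lexicographically smallest id, which makes the operation independent of
input order. Pairs overlapping at fewer than 12 loci are never compared:
with highly polymorphic markers the sibling identity probability
(P_ID-sibs, computed per locus as 0.25 + 0.5·Σp² + 0.5(Σp²)² − 0.25·Σp⁴
and multiplied across loci) only becomes negligible past roughly a dozen
loci.

## Diversity and differentiation

Expected heterozygosity uses the small-sample correction
H_E = 2n/(2n−1)·(1 − Σp̂²) with 2n typed gene copies. Hardy–Weinberg
equilibrium is tested by a Monte-Carlo exact test: the 2n gene copies are
shuffled and re-paired (default 10 000 shuffles), and configurations are
ordered by their conditional probability given the allele counts — only
the heterozygote count and the genotype multiplicities enter, since all
other terms are fixed under shuffling. The +1-corrected p-value is used
throughout, so p > 0 always. This choice handles 16-allele loci where full
enumeration is infeasible; calibration (approximate uniformity of p under
HW sampling) is asserted in the tests.

**Weir–Cockerham θ.** Per locus and allele, the standard variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from sample sizes, allele
frequencies and observed heterozygote frequencies; the multilocus estimate
is the ratio of summed components Σa / Σ(a+b+c) — not a mean of per-locus
ratios, which would be biased at weakly informative loci. Standard errors
are leave-one-locus-out jackknives; significance, when requested, comes
from permuting individuals between the two populations.

**Allele-sharing distance.** For every inter-population pair of
individuals and locus, the shared proportion is
Σ_alleles min(count₁, count₂)/2; averaging over loci, then over pairs,
gives p̄s, and D_SP = −ln(p̄s) by default. The log form is unbounded above
and behaves like a distance for very dissimilar populations; the bounded
1 − p̄s variant is also available since allele-sharing software reports
several transforms. SEs are locus jackknives.

**Relatedness.** The pair likelihood mixes the genotype-pair probabilities
conditional on sharing 0, 1 or 2 alleles identical by descent, maximized
over the (k₀, k₁, k₂) simplex by a 0.02 coarse grid plus SLSQP refinement
(log-likelihood tolerance 1e−10); r = k₂ + k₁/2. Relationship categories
compare the likelihood at the canonical points U(1,0,0), HS(.5,.5,0),
FS(.25,.5,.25), PO(0,1,0). Because the estimate is constrained to the
simplex, r̂ ≥ 0 and the null (unrelated) mean carries a small positive
boundary bias that shrinks as markers become more informative — the tests
assert a small mean and near-zero median rather than an exactly zero mean.
Frequencies can be pooled over all individuals or taken from the pair's
population; both modes are exposed.

## Assignment and migrant detection

The assignment criterion is the Rannala–Mountain posterior predictive:
with a Dirichlet(1/k) prior per locus (k = alleles observed across all
populations), the probability of drawing the genotype's two alleles
sequentially from a population with counts n_a is
(n_a + 1/k)/(n + 1) · (n_b + 1/k + δ_ab)/(n + 2), ×2 for heterozygotes,
multiplied over typed loci. The prior guarantees a finite likelihood for
alleles unseen in a reference population. An individual's own alleles are
removed from its home population's counts before scoring it there
(leave-one-out), so small samples do not self-inflate.

The migrant statistic is Λ = log₁₀(L_max / L_home) ≥ 0 — zero when home is
the likeliest origin, large when some other population explains the
genotype better. The null distribution per home population resamples
10 000 multilocus genotypes from the observed allele frequencies (with
replacement — a Monte-Carlo null, not a parametric Dirichlet draw) and
scores them identically; p_resident is the upper-tail fraction of null Λ
at or above the observed value (ties counted, +1 correction), flagged at
α = 0.01. Simulated genotypes are scored without leave-one-out, which
makes the test slightly anti-conservative for very small reference
samples — the known behaviour of resampling migrant detection at low
sample sizes, and the reason the likelihood-ratio detector flags more
individuals than the population-prior posterior on the same data.

The population-prior model scores each individual under: resident (prior
1 − ν), F0 migrant from each other population (ν/2 split equally), and F1
with one migrant parent (ν/2 split equally); the F1 locus likelihood sums
over which parental population contributed which allele. Posteriors are
normalized per individual and reported for each ν in
{0.01, 0.02, 0.05, 0.1}; the flag threshold is migrant probability > 0.9.
Deeper ancestry (grandparents) is out of scope. Assignment-derived
migration-rate matrices are row-stochastic: hard calls send a flagged
individual's mass to its assigned population; posterior input spreads the
F0 mass over sources (F1 mass stays home).

## Resistance layers

All layers live on one km-resolution grid and are linearly rescaled to
[1, 100] (v → 1 + 99·(v − min)/(max − min); constant layers become all 1).
Construction rules:

* **Habitat** — habitat-class cells form 8-connected patches; patches
  > 10 km² are retained, get resistance 1, and the Euclidean distance
  transform from them (km) is rescaled for everything else.
* **Tree cover** — percent cover, inverted (bare → 100, densest → 1).
* **Settlements** — illuminated cells (radiance > 0) are sources; the
  distance transform is inverted (adjacent → 100, farthest → 1). Cells
  with radiance > 20 are urban centres. All illuminated pixels, not only
  urban ones, act as distance sources; a flag could restrict this.
* **Roads** — per-cell density in km of road per km², by exact segment
  clipping against cell boundaries; no roads → 1.
* **Study area** — cells within 30 km of a retained patch and not urban;
  everything else becomes nodata in every layer, and urban cells are
  thereby removed from the circuit graph entirely (absolute barriers)
  rather than given resistance 100.
* **Combination** — unweighted cell-wise mean of rescaled layers, then
  rescaled again; weights are exposed but default equal, since no standard
  exists for multi-element surfaces.

## Circuit theory

A resistance raster becomes a conductance graph: 8-neighbour edges with
conductance 1/(d·(r_i + r_j)/2), d = √2 on diagonals. The
averaged-resistance form is one of the two conventions circuit-based
connectivity tools offer; it is the default here. Population regions are
short-circuited into supernodes. One node per connected component is
grounded and the reduced Laplacian factorized once (sparse LU); each pair
then needs a single solve, and R_eff = φ_A − φ_B for unit injected
current. Per-node current is half the sum of absolute incident edge
currents (focal nodes carry the full injected ampere). Against a dense
pseudo-inverse oracle the solver agrees to ~1e−13 on 10×10 grids.

Source strengths (census counts) cannot change effective resistance — the
network equations are linear in the injected current — so they enter two
explicitly labelled ways: per-pair weights s_i·s_j / mean(s_i·s_j) on the
cumulative current map, and a strength-normalized matrix
R′ = R/(s_i·s_j). Both are emitted; downstream tests can consume either.

## Mantel tests

Matrices are vectorized to the upper off-diagonal when symmetric and to
all n(n−1) off-diagonal entries when asymmetric (migration-rate matrices);
significance permutes the second matrix's row and column labels jointly.
For n ≤ 7 all n! permutations are enumerated and the p-value is exact
(identity included, so p > 0); otherwise the +1-corrected Monte-Carlo
p-value is used. The partial test residualizes both matrices on the
conditioning matrix entrywise and permutes the residualized second matrix
(Smouse–Long–Sokal). Isolation-by-distance tests build the Euclidean
distance matrix from population centroids. Rate matrices enter as
1 − rate, oriented as distances.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a six-population microsatellite study: sample sizes
(5, 7, 5, 16, 15, 7), 14 loci with 5–16 alleles (mean 11.7), and pairwise
F_ST in the 0.03–0.22 band.

* **F-model.** Ancestral frequencies are flat-Dirichlet; each population
  draws from Dirichlet(p_anc·(1−F)/F), so E[F_ST] = F and Weir–Cockerham θ
  recovers F to within 0.02 over 20 seeds. Default F = 0.12, inside the
  study band. There is no mutation, no isolation-by-distance within the
  F-model, and divergence is exchangeable across populations.
* **Genotypes** are Hardy–Weinberg within populations; migrants are F0 by
  construction (a destination-labelled individual redrawn from the source
  frequencies). Replicates add allelic dropout and false alleles at
  configurable rates.
* **Landscape.** Habitat blobs around well-separated centres, smooth
  tree-cover fields boosted inside habitat, settlement point kernels
  (some above the urban threshold), border-to-border roads, and optional
  barriers: a settlement ring around a patch (optionally urban-cored with
  a lit gap) or a settlement band between two patches.
* **Forward gene flow.** Deterministic migration mixing followed by
  binomial drift of 2N_e gene copies per generation; defaults N_e = 100,
  T = 200 generations. The migration matrix is derived from circuit
  resistance on the settlement surface as m_ij = m0·exp(−R_ij/τ), with
  m0 = 0.02 and τ = half the mean off-diagonal resistance — chosen from
  drift-migration balance (F_ST ≈ 1/(4N_e m + 1)) so connected pairs sit
  near 0.03–0.08 and a walled-off population near 0.2, matching the study
  band.

Passing tests on these data demonstrate the statistical machinery —
estimator accuracy, null calibration, power against planted signal, solver
correctness — under idealized conditions: no null alleles, stutter,
linkage, population growth or continuous (non-patch) habitat. They do not
validate ecological conclusions about any real landscape.

## The end-to-end landscape experiment

The validation experiment plants a settlement barrier around one
population, drives gene flow by the settlement resistance surface, and
asks whether the settlement layer then attains the top Mantel r² among
single layers against D_SP, with no significant isolation by distance.
The second property holds robustly (≈ 0.9–1.0 of seeded runs). The first
holds only in ≈ half the runs, and the package documents this as a genuine
limit of the design rather than hiding it: on a two-dimensional lattice,
effective resistance is insensitive to local resistive obstacles (parallel
paths short them out, and layers are capped at 1–100), so a settlement
wall expressed through the distance-based layer construction shifts
pairwise resistance by only ~1–2 SD of its background variation; the one
strong barrier available — urban masking — removes cells from *every*
layer's graph, so the walled pair's detour raises all layers' resistances
together, and Pearson-based Mantel r², being scale-free, lets nearly flat
layers (e.g. roads) track the walled-pair signature as well as the
settlement layer itself. Detecting which layer drives connectivity from
six populations is, in this precise sense, statistically marginal at this
scale — consistent with the narrow r² margins that real studies of this
design report across candidate layers.

## Problem sizes and determinism

Default grids are 60×60 km (≈ 3 600 graph nodes; a pairwise stage over 15
layer combinations solves in ~2 s), Mantel tests on six populations are
exact (720 permutations), and the full pipeline run takes ~3 s. All
randomness flows from a single seed through named SeedSequence children;
two runs with equal configs produce byte-identical tables. Degenerate
inputs (constant rasters, monomorphic loci, disconnected region pairs,
all-missing loci) return documented values (all-1 layers, H_E = 0 with
p = 1, infinite resistance with a flag, exclusion from QI) rather than
raising, except where the result would be meaningless (θ with no
variation, empty study area).
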