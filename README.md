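# corridorgen

Landscape-genetics toolkit for fragmented wildlife populations, built around
the workflow used to study large-carnivore connectivity between protected
areas: non-invasively sampled microsatellite genotypes on one side, raster
landscape data on the other, and a chain of statistics connecting them.

It is aimed at population geneticists and conservation ecologists who need
the whole chain in one place, reproducible and testable:

1. **Genotype QC** — consensus calling from replicated amplifications with a
   per-sample quality index (retain QI ≥ 0.75), and unique-individual
   identification from samples typed at ≥ 12 loci.
2. **Diversity and differentiation** — alleles per locus, unbiased expected
   heterozygosity H_E = 2n/(2n−1)·(1 − Σp²), observed heterozygosity,
   Monte-Carlo exact Hardy–Weinberg tests, P_ID-sibs, Weir–Cockerham
   θ (F_ST) with locus-jackknife SEs, and the allele-sharing distance
   D_SP = −ln(p̄s) that responds to recent gene flow, plus maximum-likelihood
   pairwise relatedness (k₀, k₁, k₂; r = k₂ + k₁/2).
3. **Migrant detection** — Rannala–Mountain posterior-predictive assignment
   likelihoods, the first-generation-migrant statistic
   Λ = log₁₀(L_max / L_home) with a Monte-Carlo resampling null
   (10 000 simulated residents per population, α = 0.01), and a
   population-prior posterior over resident / F0-migrant / F1 hypotheses
   under migration priors ν ∈ {0.01, 0.02, 0.05, 0.1}.
4. **Resistance surfaces** — habitat-patch proximity (patches > 10 km²),
   percent tree cover (inverted), settlement proximity from night-light
   rasters (cells > 20 are urban and masked out), and road density, each
   rescaled to [1, 100] on a common grid with a 30-km habitat buffer.
5. **Circuit-theory connectivity** — effective resistance between population
   polygons on the conductance graph of any resistance surface (sparse
   Laplacian solves; populations short-circuited into supernodes), with
   cumulative current maps and census-count source-strength weighting.
6. **Mantel tests** — simple and partial permutation Mantel tests between
   genetic and resistance/distance matrices, with exact enumeration for
   n ≤ 7 populations, plus isolation-by-distance tests and r²-ranked layer
   tables.

A first-class synthetic-data module (`corridorgen.simdata`) generates every
input with known ground truth — an F-model for allele frequencies whose
divergence parameter *is* the expected F_ST, Hardy–Weinberg genotypes,
planted F0 migrants, replicate calls with dropout and false alleles,
landscapes with habitat patches, settlements, roads and tree-cover
gradients, and a forward migration–drift simulator coupling gene flow to
landscape resistance.

## Worked example

```python
from corridorgen import pipeline

report = pipeline.run(pipeline.RunConfig(seed=1))
print(report.fst.round(3))
print(report.mantel_dsp.head(2).to_string(index=False))
print(report.migrants[report.migrants.flagged]
      [["id", "sampled", "assigned", "lambda", "p_resident"]].head(3))
```

The run simulates a six-population study system (sample sizes 5, 7, 5, 16,
15, 7) on a 60×60-km landscape in which a settlement ring encircles the
first population, derives gene flow from the settlement resistance surface,
and pushes the genotypes through QC, differentiation, migrant detection and
the Mantel stage. It prints:

```
       pop1   pop2   pop3   pop4   pop5   pop6
pop1  0.000  0.162  0.205  0.214  0.169  0.222
pop2  0.162  0.000  0.063  0.066  0.064  0.081
pop3  0.205  0.063  0.000  0.103  0.086  0.098
pop4  0.214  0.066  0.103  0.000  0.057  0.130
pop5  0.169  0.064  0.086  0.057  0.000  0.117
pop6  0.222  0.081  0.098  0.130  0.117  0.000

              layer        r       r2        p
settlements+habitat 0.886937 0.786657 0.011111
        settlements 0.886082 0.785142 0.012500

         id sampled assigned     lambda  p_resident
0   pop1_i1    pop1     pop4  11.228343      0.0001
8   pop2_i4    pop2     pop5   0.730202      0.0007
10  pop2_i6    pop2     pop6   7.012652      0.0001
```

Reading the output: the walled-off `pop1` is the most differentiated
population (pairwise θ 0.16–0.22 versus 0.06–0.13 elsewhere);
settlement-based resistance layers carry the highest Mantel r² against the
allele-sharing distance; and the migrant table lists individuals whose
multilocus genotype is far likelier elsewhere than at home (large Λ, small
resampling p), including the four migrants the simulator actually planted
(`pop1_i1` was planted from `pop4` and is recovered with
Λ = 11.2, p_resident = 0.0001).

`corridorgen` also installs a small CLI (`corridorgen run|dedupe|migrants|mantel`)
over the same functions.

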