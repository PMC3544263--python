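# Methods

This note records the models and estimators `hitchmap` implements, the
defaults that matter, the numerical choices, and what the synthetic-data
machinery does and does not emulate.

## Data model

Genotypes are unordered diploid allele pairs with positive integer codes;
any call containing code 0 is wholly missing (Genepop cannot represent
half-calls). All statistics are complete-case per locus: an individual
missing at a locus is dropped for that locus only. Loci are classified
dataset-wide as biallelic SNPs (≤ 2 observed alleles) or multiallelic
microsatellites. The marker map uses the female-map centimorgan position
as the canonical coordinate; male positions are stored but unused,
because dam-map positions are the tabulated standard for the salmon panel
this targets and modelling male recombination suppression is out of
scope. Loci absent from the map are retained for single-locus tests and
excluded from clustering and simulation.

## Diversity and Hardy–Weinberg

Gene diversity is Nei's unbiased estimator H = n/(n−1)(1 − Σ pᵢ²) with n
counted in gene copies (the FSTAT convention); it is undefined below two
copies. The HWE exact test conditions on the observed allele counts:
biallelic loci are tested by full enumeration over heterozygote counts
(Levene/Haldane distribution, two-sided by summing outcomes no more
probable than the observed one, with a 1+1e−12 relative tolerance so
floating-point noise cannot split probability ties); loci with more
alleles use a Monte-Carlo shuffle of the gene-copy pool (default 10,000
shuffles, seeded, add-one P-value) ordered by the conditional table
probability, of which only the terms h·log2 − Σ log(count!) vary under
shuffling. The screen is reported per locus × sample at the 1% level
without correction; the multiple-testing expectation (≈ 1% of tests) is
the reference point for interpreting the count.

## Weir–Cockerham θ

Differentiation between the two samples of a pair uses the 1984
variance-component estimator with r = 2 populations, summed over alleles:
a (between populations), b (among individuals within populations), c
(within individuals), with θ̂ = a/(a+b+c) per locus and the multilocus
estimate as the ratio of summed components — never the mean of per-locus
ratios. Loci monomorphic across both samples, or untyped in either, are
flagged uninformative and excluded from the sums (treating them as zero
would deflate pair means in the clustering test). The estimator can be
legitimately negative when between-population variance is below its
sampling expectation. Significance of the multilocus θ comes from
shuffling whole multilocus individuals between the two samples (add-one
P; minimum 100 permutations, default 1000).

## lnRH

lnRH = ln{[(1/(1−H₁))² − 1]/[(1/(1−H₂))² − 1]} with H the unbiased gene
diversity above (consistency with the reported diversity estimates), so
the statistic is antisymmetric in the two populations and mutation-model
free. Monomorphic loci need a correction before the log-ratio is finite:
when a locus is monomorphic in exactly one sample, that sample's H is
recomputed after adding a single copy of a novel allele to its gene-copy
pool (giving H = 2/(n+1)); a locus monomorphic in both samples is
uninformative and excluded. This is a documented package choice — the
source scans do not state their handling. Standardisation pools SNPs and
microsatellites within a pair (one z axis per comparison; requires ≥ 10
informative loci and nonzero spread), the outlier flag is |z| > 1.96, and
two-sided normal P-values p = 2Φ(−|z|) feed the FDR stage.

## Clustering along the map

Within each linkage group, mapped informative loci are sorted by female
cM (ties keep map input order) and consecutive pairs formed; the pair
statistic is the arithmetic mean of the two per-locus values (θ, or
|lnRH|). The null shuffles the per-locus values across **all** mapped
positions genome-wide — not within linkage groups — keeping the map
fixed, recomputes all pair means per permutation (default 5,000, minimum
1,000), and pools everything into a single null distribution whose 95th
percentile is the significance threshold; per-pair P-values use the
add-one rule against the pooled null, with a 1e−9 tolerance on the ≥
comparison so floating-point noise in the two possible summation orders
of a tied pair mean cannot split ties. Genome-wide exchange matches the
outlier-test null that extreme loci occur randomly in the genome; a
per-linkage-group null would be an alternative reading, and is not
implemented. Adjacent pairs overlap (a sliding window of width 2), so
pair tests are dependent; P-values are reported per pair and passed to
the FDR stage rather than Bonferroni-corrected. A constant statistic
vector yields a degenerate null: flagged, nothing significant. The merged
report annotates each pair as "both elevated" (both loci in the top 2.5%
of single-locus values) or "single-marker driven" (one above the 97.5%
empirical quantile, the other below the median).

## False discovery rates

Storey q-values per test list: π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ ∈ {0, 0.05, …, 0.90}, with the bootstrap selection rule (100 resamples,
seeded) minimising the estimated MSE around the most optimistic plug-in
π₀; the result is clamped to (0, 1]. q-values follow the step-down
q(p₍ᵢ₎) = min_{j≥i} π₀·m·p₍ⱼ₎/j, which reduces exactly to
Benjamini–Hochberg at π₀ = 1. Lists from different tests (including
externally computed outlier-test P-values read from one-column text
files) are processed separately per pair. The grid and resample count are
package defaults; the source scans do not state theirs.

## Overlap test

Under the null that every gene in the universe of N had an equal chance
of entering the n-gene candidate list, each permutation draws n genes
without replacement and counts hits in the special K-gene set; the
add-one P estimates P(overlap ≥ x), and the exact hypergeometric tail is
computed alongside as a cross-check. Default 10,000 permutations. For the
salmon case the counts are N = 3557, K = 60 (1.7% of 3557, rounded),
n = 10 (distinct annotated candidate genes), x = 2.

## Forward simulator

Discrete-generation diploid Wright–Fisher with viability selection:
each offspring draws two parents independently with probability
proportional to fitness (selfing possible; mating-system detail is
deliberately minimal), each parent transmits one recombinant gamete.
Crossovers are independent per marker interval with Haldane's
r = (1 − e^(−2d))/2 (d in Morgans), no interference, female-map distances
applied to both sexes; intervals crossing linkage-group boundaries get
r = 0.5. Mutation is off — on a 5–8 generation timescale, selection acts
on standing variation only. Fitnesses are (1, 1−hs, 1−s) for the
favoured allele, which is the minor allele of the selected locus in the
ancestral pool; defaults s = 0.6, h = 0.5 give (1, 0.7, 0.4). The split
experiment founds an ancestral population of Ne diploids from a source
sample (sampling individuals with replacement, or exact k-fold tiling for
count-preserving tests) followed by a default 3 generations of random
mating, splits it into a neutral wild deme and a captive deme under
selection, evolves both for t generations in complete isolation, and
reads out per-locus and multilocus θ from 16-diploid samples; 25
replicates by default. Ne comes from the drift relation Ne = t/(2F_ST)
(rounded), the same inversion used to parameterise the empirical pairs
(IRL 8/330, SWE 5/65, CAN 5/238).

Two sampling details matter and are deliberate:

- **The deme sample is an offspring cohort.** Sampling 16 diploids
  without replacement from a deme of only 65 gives allele-frequency
  estimates less sampling variance than the θ estimator's i.i.d. sampling
  model assumes, and biases replicate-mean θ ≈ 20% low. Real samples of
  16 fish come from populations far larger than their effective size, so
  the simulator samples each deme by generating 16 offspring whose
  gametes are i.i.d. draws from the deme gene pool; drift-only
  replicate means then match 1 − (1 − 1/(2Ne))^t closely.
- **Hitchhiking requires founder LD.** An ancestral population drawn
  directly from allele-frequency spectra is in linkage equilibrium, and a
  completely linked flanking marker then shows no hitchhiking at all.
  Founding from a small genotype sample (~32 haplotypes), as the field
  design does, carries real LD. For controlled experiments,
  `founder_sample_linked` builds founder samples whose flanking markers
  copy the selected locus's minor/major state with a configurable
  probability (1 at 0 cM, decaying with distance), emulating the LD of
  tightly linked markers in a real population.

## Synthetic data

Defaults reproduce the empirical study conditions: 261 biallelic SNPs and
70 microsatellites placed uniformly on 31 linkage groups whose spans sum
to 2000 cM; three wild/reared pairs with (Ne, t) = (330, 8), (65, 5),
(238, 5); 16 diploids per sample. SNP ancestral minor-allele frequencies
are 0.5 × Beta(a, b), truncated below at 0.01, with per-pair shapes
(1.6, 2), (1.0, 2.5), (0.6, 3.5) chosen so the expected sampled SNP gene
diversities sit near the three empirical levels (≈ 0.32, 0.22, 0.125).
Microsatellites draw k ~ Uniform{2..20} alleles with symmetric
Dirichlet(0.35) frequencies, putting mean diversity near 0.6 with the
full 0.2–0.9 spread. Each dataset founds from a 16-diploid source sample
(3 burn-in generations), runs the split model, and writes Genepop + map
TSV + truth JSON. Planted sweeps pick a common SNP (MAF ≥ 0.1) whose
nearest same-group neighbour is closest, and plant founder LD around it
decaying as exp(−d/1 cM).

What the generator does **not** emulate: genome-wide background LD away
from planted loci (neutral loci are in linkage equilibrium at founding),
microsatellite mutation (irrelevant over 5–8 generations), SNP
ascertainment bias, missing-data patterns (generated data are complete),
and population structure beyond the two-deme split. Passing tests
therefore show the statistics behave correctly under drift + isolated
sweeps with clean data, not that they are robust to demographic
misspecification or genotyping artefacts.

## Evidence merging

A locus is a candidate when flagged by ≥ 2 of: single-locus θ in the
empirical top 2.5%, |z_lnRH| > 1.96, membership in a significant θ pair,
membership in a significant |lnRH| pair; external outlier calls can be
merged as an additional column. Candidate regions are contiguous runs of
flagged loci reported as cM spans. Note the four flags are positively
correlated at drift-extreme loci, and the θ-quantile flag marks ~2.5% of
loci by construction, so even neutral data yield a few multi-flag
candidates — which is exactly why the q-value stage reports the expected
false-discovery burden instead of treating flags as findings.

## Problem sizes used in tests

The test suite scales Monte-Carlo sizes to what the properties need:
drift-recovery checks use 50-locus panels with 200 replicates, clustering
calibration uses 1,000 permutations, the published-quantity checks use
the stated designs (10,000 overlap draws; 500 replicates × 300 loci for
the drift θ; 25 replicates for the hitchhiking contrast). Seeds are fixed
throughout; every permutation and simulation API takes an explicit seed
and is bit-reproducible under it.
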