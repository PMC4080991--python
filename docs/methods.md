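# Methods

## Model and assumptions

A pollinium is treated as a faithful copy of its donor's diploid genotype:
all grains in a packet come from one flower, and genotyping error beyond
locus dropout is ignored. Classification is exact-match over co-genotyped
loci — a pollinium is *self* iff its unordered diploid genotype equals the
maternal stem's at every locus scored in both; any allele difference at any
shared locus is *outcross*. Loci missing in either sample carry no
information and are excluded; a pollinium sharing no locus with its
maternal stem is unclassifiable and is excluded with a count in the run
manifest. Under this rule a self pollinium can never be classified
outcross, so all misclassification is one-directional: outcross pollinia
matching the maternal genotype by chance.

That one-directional error is what the chance-match probability α and the
method-of-moments step correct. If the true selfing rate is S and an
outcross pollinium chance-matches with probability α, the expected observed
self fraction is S + (1 − S)α; inverting gives

    S_m = (S_d − α) / (1 − α).

The cited estimator family for this correction does not print a closed
form for the pollinium case, so this reconstruction — the standard
misclassification inversion — is a documented design choice of this
package. Its limits anchor it: S_m = S_d when α = 0, and S_m = 0 when
S_d = α (every observed match explainable by chance).

α is computed from *counted* pollen-pool diploid genotype frequencies, not
Hardy–Weinberg products: clonal structure and selfing both violate HWE, and
the pollen pool is directly observed (the genotyped inserted pollinia).
Each distinct pollinium multilocus genotype contributes its per-pollinium
weight times the product over its genotyped loci of the pool frequency of
its unordered diploid genotype. Per-inflorescence weighting (each visited
inflorescence counts once, its pollinia sharing the weight) is available
via `alpha_weighting="inflorescence"`; per-pollinium is the default because
the pollinium is also the bootstrap resampling unit. A maternal-stem
frequency basis is available via `freq_basis="maternal"` for studies whose
maternal sample better represents the local pollen cloud.

## Round-robin frequencies in clonal populations

Counting allele frequencies over stems underestimates genotypic diversity
(a large clone dominates); counting over distinct genotypes inflates rare
alleles (a unique genotype seen once on one ramet counts as much as a
clone of thousands). The round-robin estimator tabulates locus k over one
representative per distinct-genotype class formed on *all loci except k*,
so identity at the focal locus never drives its own collapsing.

Missing-data collapsing rule: classes are defined by the samples complete
at the retained loci; a sample with missing calls joins a class only when
it matches exactly one class at every co-genotyped locus, and otherwise
stands alone. This is deliberately conservative against over-collapsing,
which would re-inflate rare alleles — the very bias the method removes.
Round-robin needs ≥ 2 loci; single-locus data fall back to naive counting
with an explicit error/warning.

## Control partitioning

Bagged control inflorescences measure through-bag contamination. For each
visitor taxon the "total" pool is its genotyped pollinia plus all control
pollinia; r_p is the visitor share of that pool. Both α and the direct
outcrossing rate t are partitioned as
x_p = (x_T − (1 − r_p) x_c) / r_p, valid on the printed domain
x_T > x_c (1 − r_p). Small samples can breach the domain; the default
`clamp` policy clamps the partitioned rate into [0, 1] and flags the
estimate, while `error` aborts. With no controls, r_p = 1 and every
partition is the identity (S_dp = 1 − t_dT). Control pollinia are scored
against the same pollen-pool frequency table as visitor pollinia — a
control-specific table would rest on a handful of through-bag insertions.

The per-maternal-genotype S_dp table pools t_dT across all inflorescences
sharing a genotype (per taxon), partitions against the control pollinia of
that same genotype where any exist, and averages display sizes across the
distinct visited inflorescences. The table is exported for external
display-size regressions (quasi-binomial GLMM or similar); no GLM/GLMM
fitting happens in this package.

## Effectiveness, importance, SICPI

PE is computed per visit — max(0, count/inflorescence_size − control mean
per flower) — then averaged per taxon, rather than pooling counts over
pooled flowers; the permutation test operates on exactly that per-visit
vector. The control subtraction is per flower because PE is defined per
focal-inflorescence flower. Relative abundance multiplies nocturnal visit
counts by the diurnal:nocturnal sampling-effort ratio before normalizing;
the ratio is a required study-design input (default 1.0) because it cannot
be recovered from the tables. SI enters as 1 − self_compatibility with
self_compatibility defaulting to 0.05 (a conservative literature value for
strongly self-incompatible milkweeds). The insertion-side index is
parenthesized as SICPI_I = PI_I·(1 − S_mp·SI) — the only reading that
reduces to PI when selfing or incompatibility vanishes and that matches the
subtractive removal-side form SICPI_R = PI_R − PI_I·S_mp·SI, which is
clamped at zero with a flag.

## Resampling

* **Bootstrap**: B = 1000 with-replacement resamples at original size, the
  inserted pollinium as the unit (per-inflorescence arrays via
  `resample_unit="inflorescence"`; most inflorescences receive a single
  insertion, so the two choices differ little). Mean/SD of replicates are
  the reported mean/SE; the 95% CI is the 25th/975th ranked replicate at
  B = 1000, generalized to the ⌈0.025B⌉-th and ⌊0.975B⌋-th order statistics.
* **Chain bootstrap**: the frequency table is held at its point estimate
  while pollinia are resampled; re-tabulating per replicate would mix
  frequency-estimation noise into a quantity the method treats as a
  plug-in, and with the round-robin collapse it is also the dominant cost.
  Replicates that breach a partition domain (or lose every visitor
  pollinium) are *dropped and counted*, not clamped: clamping inside the
  loop shrinks the replicate spread and biases the SE toward zero. Dropped
  counts are reported so instability is visible.
* **Pairwise comparison**: B independently indexed replicate differences
  a_i − b_j (independent draws, not aligned pairs — the two bootstraps
  resample different record sets); significant iff the positive count
  exceeds 0.975B or falls below 0.025B. Ties count as not-greater. When
  drops make two replicate vectors unequal, they are truncated to the
  common length before pairing.
* **Permutation tests**: add-one Monte-Carlo p = (1 + #{perm ≥ obs})/(B+1),
  absolute mean difference for two groups, count-weighted between-group
  variance for k > 2. Degenerate (constant) data give p = 1 automatically.
* **Product CIs**: PI and SICPI replicates are built replicate-wise from
  component bootstraps (effectiveness × abundance, combined with the S_mp
  replicates via the SICPI expressions), ranked for the CI. Components must
  share B; an S_mp vector shortened by dropped replicates is padded back to
  B by resampling its survivors with a seeded generator.

All child seeds derive from `rng_seed` through named `SeedSequence`
spawns, so identical inputs and seed give byte-identical result files.

## Synthetic-data generator

The generator emulates: a clonal population (geometric ramet counts, mean
20, over 22 genets — the scale of the motivating study's unique maternal
genotypes), 4-locus genotypes with Dirichlet or uniform allele frequencies
(6 alleles/locus default), taxon-specific visitation (default three taxa
with visit counts 75/271/43 and per-flower insertion/removal probabilities
matched to observed per-visit means), logit-linear selfing in display size
(intercepts solved so marginal selfing sits near 0.88/0.49/0.41 at the mean
inflorescence size, mirroring the reported per-taxon rates), per-locus
genotyping dropout, and Poisson through-bag contamination on bagged
controls with a separate selfing intercept (`control_beta0`, default 0 →
0.5, since no field estimate of through-bag selfing exists). Outcross
donors are drawn genet-uniformly by default; `donor_weighting="ramet"`
draws stems instead, and a same-genet draw counts as (geitonogamous) self —
modelling spatially aggregated clones with high self-pollen carryover.

What it does *not* emulate: spatial foraging paths, nectar dynamics,
pollinium-load feedback on behavior, genotyping error beyond dropout,
linkage or null alleles, and family-level heterogeneity within a visitor
taxon. Passing recovery tests therefore show the estimators invert the
stated generative model, not that field data satisfy that model.

## Numerical choices and degenerate inputs

* All rates live in [0, 1] as proportions; percentages only at display.
* Partition/MoM domain violations: clamp + flag by default, `error` policy
  available; inside bootstrap loops always drop + count (see above).
* α_dp = 1 (no exclusion information) is an error, not a clamp.
* Empty control sets: zero-contamination assumption with a prominent
  warning, r_p = 1.
* A locus with no genotyped samples is omitted from frequency tables with
  a warning; fully missing genotypes are rejected at construction.
* Unordered diploid pairs are stored sorted, so A/B ≡ B/A everywhere.
* Validation caps insertions and removals at 5 per open flower (five
  pollinaria and five stigmatic slits per flower).

## Problem sizes

Default test and acceptance runs use studies of roughly 400–550 genotyped
pollinia over three taxa, B = 1000 bootstraps, 200 null repetitions for
pairwise-test calibration and 500 for permutation calibration; the
parameter-recovery checks use ~500 pollinia per taxon across 10 seeds.
These sizes put binomial sampling error well inside the asserted
tolerances while the whole suite stays quick on a single CPU.

## Known limitations

* The MoM formula is a reconstruction (see above); alternative corrections
  from the same family differ at second order in α.
* α for a taxon with few pollinium genotypes is itself noisy; the pipeline
  reports per-taxon α so users can judge exclusion power.
* The pairwise >975/<25 rule is slightly anticonservative for very skewed
  bootstrap distributions (it is a percentile rule, not a studentized
  test); the calibration tests bound its null behavior near 5%.
* No likelihood-based mating-system estimation (MLTR-style EM) and no
  paternity assignment to specific donors — the exclusion logic here needs
  only genotype identity, not pedigree inference.
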