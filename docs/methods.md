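# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Synthetic study conditions

The generator's defaults define the study conditions used throughout the
tests: eight cohorts of 250 tumors each (2,000 samples pooled), a 22-gene
panel (the 12 core mTOR-axis genes plus the translational and
nutrient-sensing module members), and a 300-node interaction network.

* **Mutations** are independent Bernoulli draws per sample × gene at fixed
  per-cohort rates on the scale seen in pan-cancer panels (0.5–13% mutated
  per gene, with one skewed cohort per gene 10 percentage points above the
  rest so that lineage enrichment exists to detect). The exception is each
  configured exclusivity pair, whose joint distribution is drawn exactly
  from the 2×2 cell probabilities solved from the target odds ratio and the
  two marginals: for OR ≠ 1 the concordant cell p₁₁ is the admissible root
  of (OR−1)p₁₁² − [(OR−1)(p_A+p_B)+1]p₁₁ + OR·p_A·p_B = 0. Any positive OR
  is feasible for marginals strictly inside (0,1); boundary marginals raise
  an error. The default plants PTEN/PIK3CA at OR = 0.2.
* **Copy number** is a 5-category draw over {−2,−1,0,+1,+2} with a fixed
  70/30 split of amplification (deletion) mass between the low-level (±1)
  and high-level (±2) call — a GISTIC-like marginal that keeps both call
  strengths represented.
* **Expression** is unit-variance Gaussian noise plus an additive shift Δ
  (z-units) on the module genes of samples carrying each contrast's altered
  genotype. Defaults: Δ = 0.5 on the translational module for PTEN loss,
  0.3 for PIK3CA mutation on the same module, 0.3 on the nutrient-sensing
  module for RICTOR amplification. Downstream z-scoring makes the marginal
  noise distribution immaterial to the contracts, so Gaussian noise is not
  a modeling claim. Because planted effects overlap (PTEN loss and PIK3CA
  mutation both raise the translational module, and the two genotypes are
  anti-correlated by the planted exclusivity), the covariate-adjusted
  coefficient for PTEN loss recovers slightly below the planted 0.5 —
  typically ≈ 0.47 — which is the correct behavior of an additive model on
  correlated genotypes, and the recovery band (0.4, 0.6) accounts for it.
* **Network**: a Barabási–Albert backbone (attachment 3) gives the
  heavy-tailed degree profile; the five seed genes plus enough of their
  neighbors to reach 12 nodes form the planted community, which receives
  dense mutual edges with channel scores in [0.75, 0.99]. Each edge carries
  text-mining, experimental, database and co-expression scores in [0, 1],
  combined as 1 − Π(1 − s_c) and written on the conventional 0–1000 integer
  scale.
* **Reproducibility**: each artifact type (alterations, expression,
  network) draws from its own stream seeded from `rng_seed`, so a fixed
  seed yields byte-identical fixture files (regression-tested by hash)
  while individual artifacts can be regenerated independently.

What the generator does **not** emulate: mutational signatures,
subclonality, batch/purity effects, within-gene hotspot structure, or
correlation between events beyond the pairwise odds-ratio targets. Passing
tests therefore demonstrate the correctness and calibration of the
computations, not the biological validity of any nomination on real data.

## Statistical kernel

* **BH-FDR**: step-up q_(i) = min_{j≥i} p_(j)·m/j capped at 1, returned in
  input order; permutation-equivariant, q ≥ p, cross-checked against
  statsmodels. Applied per emitted table; each output's metadata JSON
  records the family size.
* **2×2 test selection**: Fisher's exact test when any expected count is
  below 5, Yates-corrected χ² otherwise. Yates' correction is defined for
  2×2 tables only, so K×2 heterogeneity tables use plain Pearson χ² (with a
  fixed-margin Monte-Carlo exact p when expected counts are small).
* **Fisher's exact test** is two-sided by the probability-mass rule (sum of
  fixed-margin tables no more probable than the observed one), verified
  against full hypergeometric enumeration. Odds ratios use the
  Haldane–Anscombe +0.5 on all cells when any cell is zero — applied to the
  estimate and its Wald CI only, never to the exact p, and flagged in the
  output. A degenerate margin yields a non-evaluable record with p = 1.
* **Mann–Whitney U** uses exact enumeration when n₀+n₁ ≤ 20 with no ties,
  otherwise the tie-corrected, continuity-corrected normal approximation.
  Effect size is Cliff's δ = (#{x₁>x₀} − #{x₁<x₀})/(n₀n₁), computed in
  O(n log n) via sorted ranks; positive δ means the carrier group is
  stochastically larger.
* **Linear models** are OLS with an intercept, the binary genotype, and
  reference-level dummies for cancer type, reported with HC1 sandwich
  standard errors and Wald 95% CIs. HC1 was chosen among the sandwich
  variants as the common default for moderately large n. Rank deficiency is
  reported with the offending columns named.

## Alteration landscape

Prevalences are percentages of evaluable samples altered per cohort.
The specificity metrics and the classifier consume the union-mode vector
(mutation ∪ role-appropriate CNA); mutation-only and amplification-only
percentages are carried as separate columns. Entropy uses the natural log
(normalization by log K makes the base irrelevant); an all-zero vector has
H = 0 and undefined τ (NaN). Classification evaluates Shared before
Tumor-specific — a broadly prevalent gene with a dominant lineage is Shared
— with ties on prevalence broken toward the larger cohort and then the
lexicographically smaller label. Heterogeneity tests run on counts
reconstructed as round-half-away-from-zero of prevalence × N (stable across
platforms), and the pan-cancer percentage pools samples (the
sample-weighted mean of cohort prevalences), which the tests verify as a
conservation identity.

## Network propagation

The walk iterates the affine map x ← (1−α)Kx + αs from x = s. Both kernels
have spectral radius ≤ 1, so the map is a contraction with fixed point
α(I−(1−α)K)⁻¹s; the reported score vector is the L1-normalization of the
iterate, which is non-negative and sums to 1 at every step and, at
convergence, equals the normalized linear solve (tested to 1e−8; observed
≈ 1e−11). Convergence is declared when the L1 change of the normalized
vector drops below 1e−10 (default), with a hard failure past 1,000
iterations. With the stochastic kernel the iteration is exactly
personalized PageRank with damping 1−α, verified against an independent
PageRank implementation.

Design choices: degrees are weighted by combined score (edges carry
confidence); seeds share mass equally, and seeds absent from the filtered
graph reallocate their mass to the remaining seeds; the whole filtered
graph is propagated by default, with an optional k-hop neighborhood
restriction for parity with neighborhood-export workflows. The symmetric
kernel is the default because it damps hub dominance; the stochastic kernel
is the variant for exact PageRank equivalence.

Degree-matched nulls replace each seed with a uniform draw from its degree
decile (bins widened when they hold fewer than two candidates) and use the
add-one empirical p = (1+#{null ≥ observed})/(n_perm+1), so the smallest
attainable p with 999 permutations is 1/1000.

The non-mutated filter annotates each candidate with the pooled percentage
of samples carrying a non-synonymous mutation or an amplification, removes
genes above 3% (and hotspot-flagged genes, reported in a side table; the
default hotspot list is empty — flags are user-supplied annotations), and
re-ranks the remainder. Score ties break toward lower degree, then the
smaller symbol. Genes without alteration data are retained with a missing
percentage and a warning, since absence of data is not evidence of
alteration.

## Activity scoring

Samples present in the alteration data but missing expression are dropped
from this stage only, with counts logged. "Loss" is operationalized as
mutation OR deletion (the tumor-suppressor encoding reused for
consistency); amplification contrasts compare against diploid, excluding
deleted samples from the comparator; mutation contrasts use the mutation
flag alone. Module activity is deliberately the plain mean z — rank-based
single-sample scorers are out of scope — and is linear, so concatenated
modules score as member-count-weighted means of their parts.

## Exclusivity

The BH family is all pairs emitted in one run. The ±1.6 clip and the
q ≥ 0.10 desaturation threshold affect display fields only; stored odds
ratios and log₂OR are unclipped. Row/column order for the heatmap comes
from average-linkage hierarchical clustering on Euclidean distances between
signed log₂OR profiles (NaN cells treated as 0 for the distance only) —
the linkage/distance pair was an open choice, fixed here and configurable.
Mutation-only and SCNA-only matrices are reruns with a restricted encoding
flag, not separate code paths.

## Orchestration and robustness

Each run directory holds exactly one manifest (tool version, effective
parameters, input digests, timestamps); identical configurations reproduce
byte-identical outputs, which is regression-tested. The robustness grid
reruns nomination over FDR ∈ {0.01, 0.05, 0.10} × α ∈ {0.5, 0.75, 0.9} ×
combined-score cutoff ∈ {0.4, 0.7} and reports the fraction of top-10
nominations shared with the primary setting (α = 0.75, cutoff 0.7); the
FDR axis annotates significance calls and does not alter the ranking.
Gene symbols are harmonized at load time through a small static alias map
(e.g. PRAS40 → AKT1S1); no live identifier service is consulted.

## Problem sizes and runtime

Default test and verification sizes — 2,000 samples per simulated study,
5,000 for exclusivity recovery, 100 replicates for effect recovery, 50 for
exclusivity recovery, 100 random graphs for the propagation oracle, 1,000
null replicates for Mann–Whitney calibration — were chosen so the full
suite and the acceptance script each complete in about a minute on one CPU
while keeping Monte-Carlo error well inside the asserted bands.

## Limitations

Heterogeneity on reconstructed counts inherits the rounding of published
prevalences; the exclusivity stage tests marginal pairwise dependence and
will absorb cohort-composition effects unless run per cohort; propagation
scores depend on the confidence cutoff and edge-weight scheme, which is why
the robustness grid is part of the pipeline rather than an afterthought.
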