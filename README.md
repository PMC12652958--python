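# mtoraxis

Pan-cancer, network-aware prioritization of mTOR-axis genes.

The mTOR pathway (mTORC1/mTORC2 and their feeder inputs from PI3K–AKT) is
recurrently altered across tumor types, but the alterations are spread over
many genes and lineages. This package implements a compact, fully
reproducible analysis pipeline for asking four questions about a gene panel
centered on *MTOR*, *RPTOR*, *RICTOR*, *EIF4EBP1*, *RPS6KB1*, *PTEN*,
*PIK3CA*, *AKT1*, *TSC1/2*, *MLST8* and *RPS6*:

1. **Which alterations are shared across cancer types and which are
   lineage-restricted?** Per-cohort alteration prevalences are summarized
   with the normalized Shannon entropy H = −Σpᵢ·log pᵢ / log K and the tau
   specificity index τ = Σ(1 − xᵢ/x_max)/(K−1), classified with prespecified
   cutoffs (Shared = ≥5% prevalence in ≥5 cohorts; Tumor-specific = top −
   second ≥ 10 percentage points), and tested for between-cohort
   heterogeneity (K×2 χ², BH-FDR).
2. **Which non-mutated genes are network-proximal to the mTOR core?**
   Random walk with restart (equivalently personalized PageRank) on a
   confidence-filtered STRING-style interaction graph: edges kept at
   combined score ≥ 0.7, adjacency symmetrically degree-normalized
   (D^−1/2 A D^−1/2), restart probability α = 0.75, seeds given equal mass.
   Steady-state influence scores are checked against degree-matched seed
   permutations, and candidates with pan-cancer alteration frequency > 3%
   (or flagged hotspot variants) are removed to leave "non-mutated but
   proximal" nominations.
3. **Does module-level expression track genotype?** Gene-wise z-scores over
   the pooled cohort, module activity as the mean z of module members,
   contrasted between genotype groups with Mann–Whitney U + Cliff's δ and
   an OLS model with cancer-type covariate and HC1 robust standard errors.
4. **Which alteration pairs are mutually exclusive or co-occurring?**
   Role-aware binarization (oncogene = mutation ∪ amplification, tumor
   suppressor = mutation ∪ deletion), all-pairs 2×2 tests (Fisher exact
   when any expected count < 5, Yates-corrected χ² otherwise), BH-FDR per
   table, and a signed log₂(odds ratio) matrix clipped to ±1.6 for display.

Every stage is driven by a synthetic-data generator that emulates
TCGA-style inputs (MAF-like mutation calls, GISTIC thresholded copy-number
in {−2..+2}, pooled expression, STRING-style weighted edges) with planted
ground truth, so the entire pipeline is testable end to end without any
data download.

## Worked example

```python
from mtoraxis import *
from mtoraxis.simulate import SEED_GENES
from mtoraxis.propagation import filter_graph

cfg = default_config(rng_seed=1)              # 8 cohorts x 250 samples
alt, truth = simulate_alteration_cohorts(cfg)
table = landscape_table(alt, genes=["PTEN", "PIK3CA", "RICTOR"])
print(table[["Gene", "Entropy", "Tau", "Class",
             "Top_Cancer", "Top_vs_Second_Diff(%)"]].to_string(index=False))

graph, net_truth = simulate_interaction_network(cfg)
pcfg = PropagationConfig(seeds=SEED_GENES)    # alpha=0.75, cutoff 0.7
scores, diag = propagate(filter_graph(graph, pcfg), pcfg)
print(scores.head(3).round(4).to_string())
print(diag["iterations"], "iterations")
```

prints

```
  Gene  Entropy   Tau  Class Top_Cancer  Top_vs_Second_Diff(%)
  PTEN    0.994 0.345 Shared       coad                    9.2
PIK3CA    0.992 0.379 Shared       luad                   15.6
RICTOR    0.981 0.503 Shared       prad                   21.2
EIF4EBP1    0.1414
RPS6KB1     0.1409
RPTOR       0.1407
15 iterations
```

All three genes are altered in every synthetic cohort above the 5% cutoff,
so they classify as Shared even where one lineage dominates (RICTOR's top
cohort sits 21 percentage points above the second — high τ, but the Shared
rule takes precedence). The propagation scores are steady-state influence
values that sum to 1 over the network; the highest-scoring nodes here are
the seed-adjacent translational effectors, reached in 15 power iterations
at the default tolerance of 1e−10.

The same stages are available from the shell:

```
mtoraxis simulate  --indir inputs --seed 1
mtoraxis run-all   --indir inputs --rundir run --seed 1
mtoraxis robustness --indir inputs --rundir run
```

`run/` then holds `landscape.tsv`, `activity.tsv` + `delta_matrix.tsv`,
`propagation_full.tsv` + `nominations.tsv` + `null_pvalues.tsv`,
`pairs.tsv` + `log2or_matrix.tsv` + the heatmap, a provenance manifest, and
the 18-setting robustness grid (FDR ∈ {0.01, 0.05, 0.10} × α ∈ {0.5, 0.75,
0.9} × combined-score cutoff ∈ {0.4, 0.7}).

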