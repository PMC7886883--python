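# amlsubtypes

Multi-cohort expression subtyping and computational drug prioritization for
*NPM1*-mutated acute myeloid leukemia (AML).

*NPM1*-mutated AML is a WHO-recognized leukemic entity, yet patients within
it differ widely in co-mutation patterns, relapse risk and drug response.
This package implements a reusable, tested version of an analysis strategy
that splits the group into two expression-defined subtypes — **primitive**
(stem-cell-signature high, worse survival) and **committed**
(myelomonocytic-differentiation high) — across several independent RNA-seq
cohorts without any cross-cohort batch correction, and then uses the
subtypes to prioritize drugs on a cell-line panel. It is aimed at
computational biologists who want to run, stress-test or extend this kind
of multi-cohort subtype discovery, and it ships a synthetic-data generator
with full ground truth so every stage is verifiable without access to
controlled patient data.

## The method

**Per-cohort consensus clustering.** For each cohort, genes with a zero
count in more than 10% of samples are removed, counts are log2-normalized
with median-of-ratios size factors, and the top-variance genes are
z-scored. Each of 100 resampling rounds draws 80% of samples and 80% of
features and partitions the samples with K-medoids (PAM: Voronoi
alternation plus swap improvement, best of 10 restarts) on the distance
d(i, j) = 1 − r(i, j), where r is the Pearson correlation of the two
samples' feature vectors. The consensus matrix entry C(i, j) is the
fraction of rounds, among those drawing both i and j, in which they
co-clustered. For each k in 2..8, final labels come from K-medoids on
1 − C, and k is chosen to maximize the mean silhouette width
s(i) = (b − a) / max(a, b) on that distance.

**Meta-clustering across cohorts.** Each per-cohort cluster is summarized
by its centroid (mean z-scored expression on the genes shared by all
cohorts). Centroids from different cohorts are linked when their Pearson
correlation is ≥ 0.5 (a permutation gate is available), and seeded
label-propagation community detection on this weighted network yields the
meta-clusters. The meta-cluster with the higher mean stemness-signature
score is annotated *primitive*, the other *committed*; samples inherit the
annotation of their cluster.

**Differential expression meta-analysis.** Per cohort, each gene's effect
is the primitive-minus-committed difference of mean log2 expression with a
Welch standard error; cohorts are combined by fixed-effect inverse-variance
weighting (meta-estimate Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ², pooled SE
√(1/Σwᵢ)), with two-sided normal p-values and Benjamini–Hochberg FDR.

**Drug prioritization.** Viability curves are fitted to the Hill equation
y = 1 / (1 + (x / EC50)^H) and summarized by AUC_d, the normalized area
under the fitted viability curve over the tested log10-concentration range
(lower AUC_d = more sensitive). An elastic-net logistic model (alpha and
lambda chosen by stratified cross-validated binomial deviance) trained on
patient subtypes predicts a primitive probability for each cell line; each
drug is ranked by the concordance index (CI) between that probability and
AUC_d across lines, with a seeded permutation p-value and BH q. CI < 0.5
means primitive-like lines are more sensitive.

**Subtype characterization.** Kaplan–Meier curves and the log-rank test
compare overall survival between subtypes; the Wilcoxon rank-sum test
compares AUC_d distributions; Matthews correlation (MCC) and the area
under the precision-recall curve (AUPRC) quantify how poorly single
mutation flags (e.g. FLT3-ITD) predict the subtypes.

## Worked example

```python
from amlsubtypes import (SimulationConfig, simulate_cohorts,
                         discover_subtypes, run_de_meta)

cfg = SimulationConfig(n_cohorts=3, samples_per_cohort=(50, 60),
                       n_genes=800, lfc_signature=1.2)
mats, meta, truth = simulate_cohorts(cfg, seed=42)
res = discover_subtypes(mats, truth.stem_up_genes, seed=42, n_reps=50)
print("meta-clusters:", res.n_meta_clusters)
print("chosen k:", {c: r.chosen_k for c, r in res.consensus.items()})
tab = run_de_meta(res)
print("genes at q<0.05:", int((tab['q'] < 0.05).sum()), "of", len(tab))
```

prints

```
meta-clusters: 2
chosen k: {'cohort1': 2, 'cohort2': 2, 'cohort3': 2}
genes at q<0.05: 89 of 800
```

Three simulated cohorts, clustered independently, each select k = 2; the
six per-cohort clusters fall into exactly two cross-cohort meta-clusters
(the planted primitive/committed split), and the fixed-effect meta-analysis
calls 89 of 800 genes differential at 5% FDR — the planted signature is
~10% of genes, and the strongest meta-estimates sit near the planted
±1.2 log2 units:

```
         meta_estimate  meta_se       z    q
G0101           -1.496    0.108 -13.804  0.0
G0602            1.261    0.093  13.579  0.0
```

The same stages are available from the shell via the `amlsub` command
(`amlsub simulate`, `cluster`, `metacluster`, `de`, `fitdrc`,
`prioritize`, `survive`), each taking `--config <yaml>` and `--seed` and
appending parameters and versions to a run log.

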