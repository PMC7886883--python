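# Methods

This note documents the models, the tunable parameters, the numerical
choices, and what the synthetic scenario does and does not establish.

## Per-cohort consensus clustering

Each cohort is processed independently, in three steps.

*Gene filter.* A gene is kept iff its fraction of zero counts is ≤
`max_zero_fraction` (default 0.10); "more than 10% zeros" is read strictly,
so a gene with zeros in exactly 10% of samples survives. Filtering is per
cohort: cohorts differ in depth and composition, and the cross-cohort
steps operate on the intersection of surviving genes anyway.

*Normalization.* Size factors are the median over reference genes of
count / geometric-mean count, the reference being genes with no zero in
any sample; when fewer than 50 such genes exist, per-sample library sizes
divided by their mean are used instead. Values are
log2(count / size_factor + pseudocount), pseudocount 1. This mirrors the
count model assumed downstream without importing a DE framework.

*Feature matrix.* The `n_variable_genes` (default 5000) highest-variance
genes on the log scale are z-scored per gene (mean 0, SD 1, ddof = 1).
Constant genes are excluded before selection. The clustering feature space
is a design choice — it is standard expression-subtyping practice and
keeps "80% of features" resampling meaningful.

*Consensus K-medoids.* The sample–sample distance is 1 − Pearson
correlation over the z-scored features; it is scale-free and consistent
with the Pearson comparison used for centroids later. Each of `n_reps`
(default 100) rounds draws ⌈0.8 n⌉ samples and ⌈0.8 g⌉ genes without
replacement and clusters them with K-medoids, best of `n_init` = 10 seeded
restarts. One run is Voronoi alternation (assign to nearest medoid,
recompute each cluster's medoid, repeat to a fixed point) followed by
greedy PAM swaps (replace a medoid by any non-medoid when that lowers the
total distance-to-medoid). The swap phase matters: alternation alone has
many fixed points, and with 10 restarts it measurably misses the optimal
medoid set even on toy instances; with swaps the implementation attains
the exhaustively-enumerated optimum on hundreds of random instances with
n ≤ 8. Cost is monotone and every step is deterministic given the seed
(per-rep generators are spawned from the master seed, so reps are
independent and reproducible).

Consensus(i, j) = co-clustered count / co-sampled count; pairs never drawn
together (probability ≈ (1 − 0.64)^100 at defaults) get a neutral 0.5 with
a warning. The matrix is symmetrized and its diagonal fixed at 1.

*Choice of k.* For each k in 2..8 the final partition is K-medoids on
1 − consensus, scored by mean silhouette width on that same distance; the
silhouette is computed on the consensus-derived distance, not the raw
distance, because k selection should score the consensus structure that
produced the labels. Ties break to the smallest k. All k share the same
resampling draws — one distance matrix per rep, clustered at every k —
which changes nothing statistically and avoids recomputing 700 distance
matrices per cohort.

## Meta-clustering

Per-cohort clusters are matched across cohorts without any between-dataset
transformation: batch effects shift genes within a cohort, but a cluster's
*centroid pattern* (mean z-scored expression on the shared gene universe,
≥ 50 genes required) still correlates with its counterpart in another
cohort. Cross-cohort centroid pairs with Pearson r ≥ `min_edge_corr`
(default 0.5) are connected; same-cohort pairs never are. An optional
permutation gate (shuffle gene labels, default 1000 permutations, keep
edges with empirical p < 0.05) replaces the fixed threshold when the
number of shared genes is small.

Communities come from asynchronous label propagation on the weighted
network. Plain label propagation is visit-order dependent, so 101 seeded
restarts are run and the most frequent partition kept (ties break to the
lexicographically smallest canonical form); isolated nodes become
singleton communities with a warning. Exactly two meta-clusters are
expected; the one with the higher mean signature score (mean over member
centroids of the mean z-score of the stemness signature genes) is labeled
*primitive*, the lower *committed*. With more than two communities only
the two extreme-score ones are labeled; an exact score tie is an error
asking for a larger signature. The signature is supplied by the user (the
generator plants one; on real data any stemness list, e.g. LSC-type
genes, fits), replacing reference-profile cellular deconvolution, which
needs an external purified-population compendium.

## DE meta-analysis

Per cohort: effect = difference of group means of log2-normalized values
(primitive − committed), SE = Welch √(s₁²/n₁ + s₂²/n₂), requiring ≥ 3
samples per group. Genes flat in both groups get the SE floored at 1e-8
and flagged. The per-cohort estimator is deliberately a simple Welch
contrast — the cross-cohort combination is the step of interest — and is
documented as a substitution for a negative-binomial GLM engine.
Combination is fixed-effect inverse-variance: weights 1/se², pooled SE
√(1/Σw), two-sided normal p, BH q. Genes absent from some cohorts are
combined over the cohorts that have them, with the count reported.
A useful sanity property holds by construction: the pooled SE never
exceeds the best single-cohort SE.

## Dose–response and drug ranking

Replicates are averaged per concentration, then y = 1/(1 + (x/EC50)^H) is
fitted by bounded least squares in u = log10(x) space: log10(EC50) ∈
[log10(x_min) − 2, log10(x_max) + 2], H ∈ [0.1, 10], started from the best
cell of a 20 × 20 grid to avoid the Hill fit's multi-modality.
Viabilities above 1.2 are clipped with a warning. A fit explaining < 5%
of the variance relative to a flat line is flagged `degenerate_flat` with
EC50 reported at the boundary (above the range for flat-high curves,
below for flat-low).

AUC_d integrates the fitted curve over the tested log10 range, normalized
to [0, 1], via the closed form ∫ y du = Δu − [softplus(H ln10 (u − u₀))]/
(H ln10), evaluated with `logaddexp` for stability; a trapezoid raw mode
exists. The direction convention is fixed and stated in output headers:
lower AUC_d = more sensitive.

The transfer model is elastic-net logistic regression with internal
standardization; alpha (mixing, default grid 0.1..1.0) and lambda (50
log-spaced values down a data-driven path from lambda_max, warm-started)
minimize mean 10-fold stratified CV binomial deviance, then the winner is
refit on all data. Fold assignment, hence the selected pair, is
deterministic given the seed. Patient and cell-line matrices are
harmonized first: gene intersection (≥ 50), constant genes dropped from
both, each gene z-scored within its own dataset — the patient/cell-line
co-normalization is otherwise unspecified territory, and per-dataset
z-scoring is the neutral choice.

Drugs are ranked by the concordance index between predicted primitive
probability and AUC_d: over pairs of lines with distinct AUC_d, concordant
orderings score 1, score ties 0.5. The default null is 1000 seeded
permutations of the probability vector, p = (1 + #{|CIperm − 0.5| ≥
|CIobs − 0.5|}) / (1 + n_perm), so p is floored at 1/1001; a tie-naive
normal approximation (Kendall-tau null variance) is available. Ranks sort
by ascending BH q, then |CI − 0.5| descending, then drug id. Probabilities
are used as continuous scores by default; passing hard labels gives the
binary-label variant.

## Survival and association statistics

Kaplan–Meier estimation and the log-rank test use standard product-limit
and observed-minus-expected machinery. The Wilcoxon rank-sum test uses
exact enumeration when the combined sample is ≤ 12 with no ties (the
switch point is configurable) and otherwise the normal approximation with
midranks, tie and continuity corrections. MCC is computed from the 2 × 2
table after dropping unassayed pairs and errors on a zero margin. AUPRC
uses the step-wise rectangular rule with tied scores grouped — published
AUPRC values differ between interpolation variants, so the variant is
fixed and named. AUPRC here treats each mutation flag as the predictor of
the primitive class, one flag at a time. A multivariable Cox model is
deliberately out of scope; the CLI emits the subtype + covariate table so
any survival package can fit one.

## Synthetic scenario

The generator plants the structure the analysis assumes, with full ground
truth. Defaults (the study conditions for every recovery test): 5 cohorts
of 60–100 samples; 2000 genes with baseline log2 means uniform on [3, 10];
10% of genes subtype-informative at ±1 log2 unit split evenly between a
stem-up (primitive) and a committed-up set, applied as ±half-effect per
subtype; per-(cohort, gene) batch shifts N(0, 0.3) on the log2 scale —
additive shifts that no within-cohort normalization removes, which is the
condition the centroid-network matching exists to handle; negative
binomial counts with dispersion 0.2; primitive prevalence 0.45. An
FLT3-ITD-like flag is drawn with class-conditional rates solved from the
phi-coefficient identity to hit MCC 0.32 at a 40% marginal frequency
(infeasible targets error). Survival is exponential with committed median
anchored at 2 years and hazard ratio 2.2 for primitive; censoring is
uniform on [0, c], with c solved numerically so the expected censored
fraction is 0.2. The cell-line panel (60 lines) uses the same expression
model with its own batch shift; each (line, drug) draws EC50 log-uniform
on [0.05, 5] µM and H uniform on [0.7, 2.5], and for the 3 active drugs
(of 20) the EC50 of primitive-like lines is moved so that the line's
noise-free AUC_d changes by exactly −0.25 (solved by root-finding on the
closed-form AUC). Viabilities are Hill values plus N(0, 0.05) noise,
clipped at 0, at 10 log-spaced doses from 0.001 to 10 µM in triplicate.

What the scenario does not emulate: gene–gene correlation structure,
count outliers and mappability artifacts, cohort-specific sequencing
protocols beyond an additive shift, informative censoring, and
within-subtype heterogeneity. Passing recovery tests therefore shows the
pipeline recovers the structure it is designed for under its own
assumptions, not that real cohorts satisfy those assumptions.

## Problem sizes used by the recovery checks

The repeated-seed checks run the default scenario at 20 seeds (subtype
recovery; drug ranking), 20 × 1000 genes under a global null and 10 seeds
at a planted 2-log2 effect with ~50 samples per arm per cohort (DE
calibration and power), and 20/40 seeds at n = 150 (log-rank power and
null calibration). The acceptance script's elastic-net leg trains on the
discovery cohort using the 1000 highest-variance harmonized genes with
alpha grid {0.2, 0.5, 0.8}, 12 lambdas and 5 folds — a scaled-down grid
that leaves the selection mechanism identical to the library defaults.
One known ceiling: with 3 active drugs against 17 inactive ones, the
Spearman correlation between the (binary) planted effect and 0.5 − CI is
at most ≈ 0.62 even when the ranking is perfect, because 17 tied values
dominate the rank correlation; the recovery checks therefore assert the
ordering itself (active drugs occupying the top ranks).

## Known limitations

Silhouette-on-consensus favours reproducible partitions; a nested or
hierarchical group structure whose k = 2 merge is always the same can
score as well as the finer truth. Label propagation on very small
networks (a handful of centroid nodes) can be unstable when edge weights
are nearly equal — the restart-majority mechanism mitigates but does not
remove this. The Welch contrast ignores count dispersion sharing across
genes, costing power at very small n relative to shrinkage estimators.
The Hill model fixes the top asymptote at 1 and the bottom at 0; screens
with partial-efficacy compounds need a 4-parameter variant, which is out
of scope.
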