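"""End-to-end orchestration of the subtype-discovery pipeline.

Thin glue over the stage modules: preprocess each cohort, run per-cohort
consensus clustering, meta-cluster the per-cohort clusters across cohorts,
annotate primitive / committed via a stemness signature, and hand the
labels to the DE meta-analysis, survival and drug-prioritization stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster, demeta, metacluster, preprocess
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SubtypeDiscoveryResult:
    consensus: dict                      # cohort_id -> ConsensusResult
    network: metacluster.MetaClusterNetwork
    subtype_map: dict
    assignments: pd.DataFrame            # cohort_id, sample_id, cluster, ...
    zscored: dict = field(repr=False, default_factory=dict)
    log_normalized: dict = field(repr=False, default_factory=dict)

    @property
    def n_meta_clusters(self) -> int:
        return self.network.n_meta_clusters

    def subtype_series(self) -> pd.Series:
        return self.assignments.set_index("sample_id")["subtype"]


def preprocess_cohort(counts: ExpressionMatrix,
                      cfg: preprocess.PreprocessConfig | None = None):
    """Counts -> (log-normalized matrix, z-scored clustering matrix)."""
    cfg = cfg or preprocess.PreprocessConfig()
    filtered = preprocess.filter_low_expressed_genes(counts, cfg)
    logm = preprocess.normalize_log(filtered, cfg)
    zm = preprocess.prepare_clustering_matrix(logm, cfg)
    return logm, zm


def discover_subtypes(count_matrices: list[ExpressionMatrix],
                      signature: list, seed: int = 0,
                      preprocess_cfg: preprocess.PreprocessConfig | None = None,
                      k_range=cluster.DEFAULT_K_RANGE, n_reps: int = 100,
                      sample_frac: float = 0.8, feature_frac: float = 0.8,
                      n_init: int = 10,
                      min_edge_corr: float = 0.5) -> SubtypeDiscoveryResult:
    """Run the discovery arm: per-cohort clustering + cross-cohort matching.

    ``signature`` is the stemness gene set used to orient the primitive /
    committed annotation of the meta-clusters.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seeds = {em.cohort_id: int(child.generate_state(1)[0] % (2**31))
                    for em, child in zip(count_matrices,
                                         ss.spawn(len(count_matrices) + 1))}
    lp_seed = int(ss.spawn(len(count_matrices) + 1)[-1].generate_state(1)[0] % (2**31))

    logs, zms, results = {}, {}, {}
    for em in count_matrices:
        logm, zm = preprocess_cohort(em, preprocess_cfg)
        logs[em.cohort_id] = logm
        zms[em.cohort_id] = zm
        results[em.cohort_id] = cluster.select_k_and_cluster(
            zm, k_range=k_range, n_reps=n_reps, sample_frac=sample_frac,
            feature_frac=feature_frac, n_init=n_init,
            seed=cohort_seeds[em.cohort_id])
        log.info("%s: chose k=%d (silhouettes %s)", em.cohort_id,
                 results[em.cohort_id].chosen_k,
                 {k: round(v, 3) for k, v in
                  results[em.cohort_id].mean_silhouette_by_k.items()})

    shared = metacluster.shared_gene_universe(list(zms.values()))
    centroids = []
    for cohort_id, res in results.items():
        centroids.extend(metacluster.compute_centroids(
            zms[cohort_id], res.labels, shared))
    network = metacluster.build_centroid_network(centroids,
                                                 min_edge_corr=min_edge_corr)
    metacluster.label_propagation_communities(network, seed=lp_seed)
    subtype_map, assignments = metacluster.annotate_subtypes(
        network, signature, {c: r.labels for c, r in results.items()})
    return SubtypeDiscoveryResult(
        consensus=results, network=network, subtype_map=subtype_map,
        assignments=metacluster.assignments_frame(assignments),
        zscored=zms, log_normalized=logs)


def run_de_meta(result: SubtypeDiscoveryResult) -> pd.DataFrame:
    """Per-cohort Welch effects combined by fixed-effect meta-analysis."""
    subtype = result.subtype_series()
    effects = {}
    for cohort_id, logm in result.log_normalized.items():
        labels = subtype[subtype.index.isin(logm.sample_ids)]
        labels = labels[labels.isin(["primitive", "committed"])]
        effects[cohort_id] = demeta.per_cohort_effect(logm, labels)
    return demeta.differential_expression_meta(effects)
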