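"""Cross-cohort meta-clustering of per-cohort expression clusters.

Each per-cohort cluster is summarized by its centroid (mean z-scored
expression over member samples, on the gene universe shared by all
cohorts). Centroids from *different* cohorts are connected when their
Pearson correlation clears a threshold; label-propagation community
detection on this weighted network yields the meta-clusters, which are
annotated primitive / committed by a stemness-signature score. This
matching step needs no between-cohort batch correction.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

MIN_SHARED_GENES = 50


@dataclass
class ClusterCentroid:
    """Mean z-scored expression of one per-cohort cluster."""

    cohort_id: str
    cluster_id: int
    gene_ids: list
    values: np.ndarray
    n_samples: int

    @property
    def node(self) -> tuple:
        return (self.cohort_id, self.cluster_id)


@dataclass
class MetaClusterNetwork:
    """Centroid-correlation network plus its community structure."""

    centroids: list
    graph: nx.Graph
    min_edge_corr: float
    communities: dict = field(default_factory=dict)   # node -> meta-cluster id
    subtype_map: dict = field(default_factory=dict)   # meta-cluster id -> label

    @property
    def n_meta_clusters(self) -> int:
        return len(set(self.communities.values()))


@dataclass
class SubtypeAssignment:
    cohort_id: str
    sample_id: str
    cluster_id: int
    meta_cluster_id: int
    subtype: str


# ---------------------------------------------------------------------------

def shared_gene_universe(zms: list[ExpressionMatrix]) -> list:
    """Gene intersection across cohorts, in the first cohort's order."""
    common = set(zms[0].gene_ids)
    for zm in zms[1:]:
        common &= set(zm.gene_ids)
    shared = [g for g in zms[0].gene_ids if g in common]
    if len(shared) < MIN_SHARED_GENES:
        counts = {zm.cohort_id: zm.n_genes for zm in zms}
        raise ValueError(
            f"only {len(shared)} genes shared across cohorts "
            f"(need >= {MIN_SHARED_GENES}); per-cohort gene counts: {counts}"
        )
    return shared


def compute_centroids(zm: ExpressionMatrix, labels: pd.Series,
                      shared_genes: list) -> list[ClusterCentroid]:
    """Per-cluster mean of z-scored values, restricted to the shared genes."""
    sub = zm.subset_genes(shared_genes)
    out = []
    for cluster_id in sorted(labels.unique()):
        members = labels.index[labels == cluster_id]
        vals = sub.values[members].to_numpy(dtype=float).mean(axis=1)
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"non-finite centroid for {zm.cohort_id}/cluster {cluster_id}"
            )
        out.append(ClusterCentroid(zm.cohort_id, int(cluster_id),
                                   list(shared_genes), vals, len(members)))
    return out


def build_centroid_network(centroids: list[ClusterCentroid],
                           min_edge_corr: float = 0.5) -> MetaClusterNetwork:
    """Connect cross-cohort centroid pairs with Pearson r >= threshold."""
    cohorts = {c.cohort_id for c in centroids}
    if len(cohorts) < 2:
        raise ValueError("meta-clustering needs centroids from >= 2 cohorts")
    M = np.vstack([c.values for c in centroids])
    if (M.std(axis=1) == 0).any():
        flat = [c.node for c, s in zip(centroids, M.std(axis=1)) if s == 0]
        raise ValueError(f"zero-variance centroid(s): {flat}")
    R = np.corrcoef(M)
    G = nx.Graph()
    G.add_nodes_from(c.node for c in centroids)
    for i, a in enumerate(centroids):
        for j in range(i + 1, len(centroids)):
            b = centroids[j]
            if a.cohort_id == b.cohort_id:
                continue
            r = float(R[i, j])
            if r >= min_edge_corr:
                G.add_edge(a.node, b.node, weight=r)
    return MetaClusterNetwork(centroids=list(centroids), graph=G,
                              min_edge_corr=min_edge_corr)


def permutation_edge_filter(network: MetaClusterNetwork, n_perm: int = 1000,
                            alpha: float = 0.05, seed: int = 0) -> MetaClusterNetwork:
    """Alternative edge gate: keep edges whose correlation beats a
    gene-label-shuffling null at empirical p < ``alpha``."""
    rng = np.random.default_rng(seed)
    lookup = {c.node: c.values for c in network.centroids}
    G = nx.Graph()
    G.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        a, b = lookup[u], lookup[v]
        perm_r = np.empty(n_perm)
        for p in range(n_perm):
            perm_r[p] = np.corrcoef(a, rng.permutation(b))[0, 1]
        pval = (1 + np.sum(perm_r >= d["weight"])) / (1 + n_perm)
        if pval < alpha:
            G.add_edge(u, v, **d)
    return MetaClusterNetwork(centroids=network.centroids, graph=G,
                              min_edge_corr=network.min_edge_corr)


def _canonical(partition) -> tuple:
    """Order-free canonical form of a node partition."""
    return tuple(sorted(tuple(sorted(map(str, com))) for com in partition))


def label_propagation_communities(network: MetaClusterNetwork, seed: int = 0,
                                  n_restarts: int = 101) -> dict:
    """Seeded asynchronous label propagation, majority vote over restarts.

    Plain label propagation depends on node visit order; we run
    ``n_restarts`` seeded replicates and keep the most frequent partition
    (ties break to the lexicographically smallest canonical form).
    Isolated nodes become singleton communities.
    """
    G = network.graph
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    isolated = [n for n in G.nodes if G.degree(n) == 0]
    if isolated:
        warnings.warn(f"{len(isolated)} isolated cluster node(s) form "
                      f"singleton meta-clusters: {isolated}", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    tallies: Counter = Counter()
    rep_partition = {}
    for child in ss.spawn(n_restarts):
        rng_seed = int(child.generate_state(1)[0] % (2**31))
        parts = list(nx.community.asyn_lpa_communities(G, weight="weight",
                                                       seed=rng_seed))
        key = _canonical(parts)
        tallies[key] += 1
        rep_partition.setdefault(key, parts)
    best = min(tallies, key=lambda k: (-tallies[k], k))
    communities = {}
    ordered = sorted(rep_partition[best], key=lambda com: sorted(map(str, com))[0])
    for cid, com in enumerate(ordered, start=1):
        for node in com:
            communities[node] = cid
    network.communities = communities
    return communities


def signature_scores(network: MetaClusterNetwork, signature: list) -> dict:
    """Per-meta-cluster mean (over member centroids) of the mean z-score of
    the signature genes."""
    genes = network.centroids[0].gene_ids
    idx = [i for i, g in enumerate(genes) if g in set(signature)]
    if not idx:
        raise ValueError("signature shares no genes with the centroid universe")
    by_comm: dict = {}
    for c in network.centroids:
        cid = network.communities[c.node]
        by_comm.setdefault(cid, []).append(float(np.mean(c.values[idx])))
    return {cid: float(np.mean(v)) for cid, v in by_comm.items()}


def annotate_subtypes(network: MetaClusterNetwork, signature: list,
                      cluster_labels: dict) -> tuple[dict, list[SubtypeAssignment]]:
    """Label meta-clusters primitive / committed by stemness-signature score.

    ``cluster_labels`` maps cohort_id -> pandas Series (sample -> cluster).
    The meta-cluster with the higher score is *primitive*. With more than
    two communities the two extreme-score ones are labeled and the rest
    left unlabeled with a warning; an exact score tie is an error.
    """
    if not network.communities:
        raise ValueError("run label_propagation_communities first")
    scores = signature_scores(network, signature)
    if len(scores) < 2:
        raise ValueError("need >= 2 meta-clusters to annotate subtypes")
    hi = max(scores, key=scores.get)
    lo = min(scores, key=scores.get)
    if scores[hi] == scores[lo]:
        raise ValueError("exact signature-score tie between meta-clusters; "
                         "supply a larger signature gene set")
    if len(scores) > 2:
        warnings.warn(
            f"{len(scores)} meta-clusters detected; labeling only the two "
            "extreme-score communities", stacklevel=2)
    subtype_map = {cid: "unlabeled" for cid in scores}
    subtype_map[hi] = "primitive"
    subtype_map[lo] = "committed"
    network.subtype_map = subtype_map
    assignments = []
    for cohort_id, labels in cluster_labels.items():
        for sample_id, cluster_id in labels.items():
            node = (cohort_id, int(cluster_id))
            if node not in network.communities:
                continue
            cid = network.communities[node]
            assignments.append(SubtypeAssignment(
                cohort_id=cohort_id, sample_id=sample_id,
                cluster_id=int(cluster_id), meta_cluster_id=cid,
                subtype=subtype_map[cid]))
    return subtype_map, assignments


def assignments_frame(assignments: list[SubtypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.cohort_id, a.sample_id, a.cluster_id, a.meta_cluster_id, a.subtype)
         for a in assignments],
        columns=["cohort_id", "sample_id", "cluster", "meta_cluster", "subtype"],
    )
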