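"""Per-cohort consensus clustering.

Resampled K-medoids: each of ``n_reps`` rounds draws 80% of samples and 80%
of features, partitions them with K-medoids on a correlation distance, and
the consensus matrix records how often two samples co-clustered among the
rounds where both were drawn. The number of clusters is chosen by mean
silhouette width on the consensus-derived distance, over k = 2..8.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_K_RANGE = tuple(range(2, 9))


# ---------------------------------------------------------------------------
# K-medoids kernel
# ---------------------------------------------------------------------------

def _kmedoids_once(D: np.ndarray, k: int, rng: np.random.Generator):
    """One PAM run from a random medoid draw: Voronoi alternation to a
    fixed point, then greedy medoid swaps until no swap lowers the total
    distance-to-medoid.

    The alternation assigns each point to its nearest medoid and
    recomputes each cluster's medoid as the member minimizing total
    within-cluster distance; the swap phase then considers replacing each
    medoid by any non-medoid point, escaping alternation fixed points.
    """
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(n * k):
        labels = np.argmin(D[medoids], axis=0)
        labels[medoids] = np.arange(k)  # a medoid always stays in its own cluster
        new = np.empty(k, dtype=np.intp)
        for c in range(k):
            members = np.flatnonzero(labels == c)
            within = D[np.ix_(members, members)].sum(axis=0)
            new[c] = members[np.argmin(within)]
        new.sort()
        if np.array_equal(new, medoids):
            break
        medoids = new
    # swap phase (cost never increases, terminates at a swap-optimal set)
    cost = D[medoids].min(axis=0).sum()
    for _ in range(n * k):
        improved = False
        for j in range(k):
            others = np.delete(medoids, j)
            base = D[others].min(axis=0) if k > 1 else np.full(n, np.inf)
            cand_cost = np.minimum(base[None, :], D).sum(axis=1)
            cand_cost[medoids] = np.inf
            o = int(np.argmin(cand_cost))
            if cand_cost[o] < cost - 1e-12:
                medoids[j] = o
                cost = cand_cost[o]
                improved = True
        if not improved:
            break
        medoids.sort()
    labels = np.argmin(D[medoids], axis=0)
    labels[medoids] = np.arange(k)
    cost = D[medoids[labels], np.arange(n)].sum()
    return labels, medoids, cost


def k_medoids(D: np.ndarray, k: int, seed, n_init: int = 10):
    """Best-of-``n_init`` seeded K-medoids restarts on a distance matrix.

    Returns ``(labels, medoid_indices)`` of the restart with lowest total
    distance-to-medoid. Deterministic given ``seed``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, n={n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, medoids, cost = _kmedoids_once(D, k, rng)
        if best is None or cost < best[2] - 1e-12:
            best = (labels, medoids, cost)
    return best[0], best[1]


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM-style K-medoids on a precomputed distance matrix.

    Parameters
    ----------
    n_clusters : int
    n_init : int
        Random restarts; the lowest-cost run wins.
    random_state : int
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        """``X`` is a square symmetric distance matrix with zero diagonal."""
        labels, medoids = k_medoids(X, self.n_clusters, self.random_state, self.n_init)
        self.labels_ = labels
        self.medoid_indices_ = medoids
        self.inertia_ = float(
            np.asarray(X)[medoids[labels], np.arange(len(labels))].sum()
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# distances and silhouette
# ---------------------------------------------------------------------------

def correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of ``X`` (samples x features)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    R = (Xc / norm) @ (Xc / norm).T
    D = 1.0 - np.clip(R, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def silhouette_width(D: np.ndarray, labels: np.ndarray):
    """Per-sample silhouette widths and their mean on a precomputed distance.

    s(i) = (b - a) / max(a, b) with a = mean within-cluster distance and
    b = mean distance to the nearest other cluster; singletons score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    widths = silhouette_samples(np.asarray(D, dtype=float), labels, metric="precomputed")
    return widths, float(widths.mean())


# ---------------------------------------------------------------------------
# consensus machinery
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Outcome of silhouette-selected consensus clustering for one cohort."""

    cohort_id: str
    k_range: tuple
    chosen_k: int
    consensus: pd.DataFrame           # samples x samples, for chosen_k
    labels: pd.Series                 # sample -> 1..chosen_k
    mean_silhouette_by_k: dict
    n_reps: int
    sample_frac: float
    feature_frac: float
    seed: int
    consensus_by_k: dict = field(default_factory=dict, repr=False)


def _resample_plans(n: int, g: int, n_reps: int, sample_frac: float,
                    feature_frac: float, seed: int):
    """Per-rep (sample subset, feature subset, k-medoids rng) draws."""
    ns = int(np.ceil(sample_frac * n))
    ng = int(np.ceil(feature_frac * g))
    ss = np.random.SeedSequence(seed)
    plans = []
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        plans.append((
            np.sort(rng.choice(n, size=ns, replace=False)),
            np.sort(rng.choice(g, size=ng, replace=False)),
            rng,
        ))
    return plans


def _consensus_for_ks(X: np.ndarray, ks, n_reps: int, sample_frac: float,
                      feature_frac: float, seed: int, n_init: int = 10):
    """Consensus matrices for every k, sharing the resampling draws.

    ``X`` is samples x features (z-scored). Returns {k: consensus array}.
    """
    n, g = X.shape
    ns = int(np.ceil(sample_frac * n))
    if ns < max(ks):
        raise ValueError(
            f"resampled draw of {ns} samples cannot support k={max(ks)}"
        )
    hit = {k: np.zeros((n, n)) for k in ks}
    tried = np.zeros((n, n))
    eye_boost = np.arange(n)
    for sub, feat, rng in _resample_plans(n, g, n_reps, sample_frac, feature_frac, seed):
        D = correlation_distance(X[np.ix_(sub, feat)])
        tried[np.ix_(sub, sub)] += 1.0
        for k in ks:
            labels, _ = k_medoids(D, k, rng, n_init=n_init)
            same = (labels[:, None] == labels[None, :]).astype(float)
            hit[k][np.ix_(sub, sub)] += same
    out = {}
    never = tried == 0
    never[eye_boost, eye_boost] = False
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pairs were never co-sampled; "
            "their consensus is set to 0.5", stacklevel=2)
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = hit[k] / tried
        C[never] = 0.5
        np.fill_diagonal(C, 1.0)
        C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(C, 1.0)
        out[k] = C
    return out


def build_consensus(zm: ExpressionMatrix, k: int, n_reps: int = 100,
                    sample_frac: float = 0.8, feature_frac: float = 0.8,
                    seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Consensus matrix for a single k (samples x samples, in [0, 1])."""
    if not (0 < sample_frac <= 1 and 0 < feature_frac <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = zm.values.to_numpy(dtype=float).T
    C = _consensus_for_ks(X, [k], n_reps, sample_frac, feature_frac, seed, n_init)[k]
    return pd.DataFrame(C, index=zm.sample_ids, columns=zm.sample_ids)


class ConsensusKMedoids(BaseEstimator, ClusterMixin):
    """Consensus K-medoids with silhouette-based selection of k.

    ``fit(X)`` takes a samples x features array of z-scored expression.
    For every k in ``k_range`` a consensus matrix is built from ``n_reps``
    resampled K-medoids runs (all k share the same resampling draws);
    final labels come from K-medoids on ``1 - consensus`` and k is chosen
    to maximize the mean silhouette width on that distance (ties break to
    the smallest k).

    Attributes (after fit)
    ----------------------
    chosen_k_ : int
    labels_ : ndarray of int, 0-based cluster labels
    consensus_ : ndarray, consensus matrix at ``chosen_k_``
    consensus_by_k_ : dict k -> consensus matrix
    mean_silhouette_by_k_ : dict k -> float
    """

    def __init__(self, k_range=DEFAULT_K_RANGE, n_reps: int = 100,
                 sample_frac: float = 0.8, feature_frac: float = 0.8,
                 n_init: int = 10, random_state: int = 0):
        self.k_range = k_range
        self.n_reps = n_reps
        self.sample_frac = sample_frac
        self.feature_frac = feature_frac
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        ks = sorted(self.k_range)
        if n < max(ks) + 1:
            raise ValueError(
                f"{n} samples cannot support k up to {max(ks)}; shrink k_range"
            )
        if not (0 < self.sample_frac <= 1 and 0 < self.feature_frac <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        consensus = _consensus_for_ks(
            X, ks, self.n_reps, self.sample_frac, self.feature_frac,
            self.random_state, self.n_init)
        final_seed = np.random.SeedSequence(self.random_state).spawn(self.n_reps + 1)[-1]
        sil, labels_by_k = {}, {}
        for k in ks:
            Dcons = 1.0 - consensus[k]
            np.fill_diagonal(Dcons, 0.0)
            labels, _ = k_medoids(Dcons, k, np.random.default_rng(final_seed),
                                  n_init=self.n_init)
            labels_by_k[k] = labels
            try:
                _, sil[k] = silhouette_width(Dcons, labels)
            except ValueError:  # degenerate single-cluster outcome
                sil[k] = -1.0
        best = max(sil, key=lambda k: (sil[k], -k))
        self.chosen_k_ = int(best)
        self.labels_ = labels_by_k[best]
        self.consensus_by_k_ = consensus
        self.consensus_ = consensus[best]
        self.mean_silhouette_by_k_ = sil
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def select_k_and_cluster(zm: ExpressionMatrix, k_range=DEFAULT_K_RANGE,
                         n_reps: int = 100, sample_frac: float = 0.8,
                         feature_frac: float = 0.8, n_init: int = 10,
                         seed: int = 0) -> ConsensusResult:
    """Full consensus-clustering pass for one cohort."""
    est = ConsensusKMedoids(k_range=k_range, n_reps=n_reps,
                            sample_frac=sample_frac, feature_frac=feature_frac,
                            n_init=n_init, random_state=seed)
    est.fit(zm.values.to_numpy(dtype=float).T)
    samples = zm.sample_ids
    return ConsensusResult(
        cohort_id=zm.cohort_id,
        k_range=tuple(sorted(k_range)),
        chosen_k=est.chosen_k_,
        consensus=pd.DataFrame(est.consensus_, index=samples, columns=samples),
        labels=pd.Series(est.labels_ + 1, index=samples, name="cluster"),
        mean_silhouette_by_k=est.mean_silhouette_by_k_,
        n_reps=n_reps,
        sample_frac=sample_frac,
        feature_frac=feature_frac,
        seed=seed,
        consensus_by_k={k: pd.DataFrame(v, index=samples, columns=samples)
                        for k, v in est.consensus_by_k_.items()},
    )
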