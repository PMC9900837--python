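"""Subsampled consensus community detection (the shared clustering engine).

Repeated graph-based clustering on subsamples of the data yields a
co-clustering matrix; agglomerative clustering on that matrix gives a
consensus partition whose cluster number is chosen by internal validation.
Each run subsamples the cells without replacement, builds a k-nearest-
neighbour graph on Euclidean distance in (z-scored) feature space, and runs
Leiden community detection with an RB-modularity objective.  Because every
cell is absent from a fraction of runs, co-clustering counts are normalised
by co-sampling counts.
"""

from __future__ import annotations

import numpy as np
import igraph
import leidenalg
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted


class ConsensusError(ValueError):
    pass


def knn_leiden_labels(X, n_neighbors=10, resolution=1.3, seed=0):
    """One clustering run: kNN graph + Leiden at the given resolution."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:] if i != j}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2,
    )
    return np.array(part.membership, dtype=np.int64)


class ConsensusLeidenClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering via subsampled kNN-Leiden runs.

    Parameters
    ----------
    n_runs : number of subsampled clustering runs.
    subsample : fraction of cells included per run (without replacement).
    n_neighbors : kNN graph degree.
    resolution : Leiden RB-modularity resolution parameter.
    k_range : inclusive (lo, hi) scan range for the consensus cluster
        number; capped at ``n_samples - 1``.
    db_tie_tolerance : relative band around the Davies-Bouldin optimum
        within which the Silhouette maximum breaks near-ties.
    random_state : master seed; identical seeds give identical labels.

    Attributes (after ``fit``)
    --------------------------
    co_clustering_ : (n, n) co-clustering frequency, normalised by the
        number of runs in which both cells were sampled.
    labels_ : consensus labels.
    n_clusters_ : chosen cluster number.
    db_trace_, silhouette_trace_ : dict k -> score over the scan.
    """

    def __init__(self, n_runs=500, subsample=0.95, n_neighbors=10,
                 resolution=1.3, k_range=(2, 30), db_tie_tolerance=0.01,
                 random_state=None):
        self.n_runs = n_runs
        self.subsample = subsample
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.k_range = k_range
        self.db_tie_tolerance = db_tie_tolerance
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = len(X)
        if self.n_runs < 2:
            raise ConsensusError("need at least 2 consensus runs")
        if n < 2 * self.n_neighbors:
            raise ConsensusError(
                f"need at least {2 * self.n_neighbors} cells, got {n}")
        rng = np.random.default_rng(self.random_state)
        m = max(2, int(round(self.subsample * n)))
        together = np.zeros((n, n), dtype=np.int64)
        sampled = np.zeros((n, n), dtype=np.int64)
        for _ in range(self.n_runs):
            sel = np.sort(rng.choice(n, size=m, replace=False))
            labels = knn_leiden_labels(
                X[sel], self.n_neighbors, self.resolution,
                seed=int(rng.integers(0, 2**31 - 1)))
            sampled[np.ix_(sel, sel)] += 1
            for lab in np.unique(labels):
                members = sel[labels == lab]
                together[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            co = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(co, 1.0)
        self.co_clustering_ = co
        self.labels_, self.n_clusters_, self.db_trace_, self.silhouette_trace_ = (
            self._consensus_labels(X, co))
        return self

    def _consensus_labels(self, X, co):
        n = len(X)
        distance = 1.0 - co
        lo, hi = self.k_range
        hi = min(hi, n - 1)
        lo = max(2, lo)
        db_trace, sil_trace, labelings, eligible = {}, {}, {}, []
        for k in range(lo, hi + 1):
            agg = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage="complete")
            labels = agg.fit_predict(distance)
            if len(np.unique(labels)) < 2:
                continue
            labelings[k] = labels
            db_trace[k] = float(davies_bouldin_score(X, labels))
            sil_trace[k] = float(silhouette_score(X, labels))
            # Singleton clusters have zero within-cluster scatter, which
            # degenerates the Davies-Bouldin index (it drifts down as
            # outliers are shaved off); such partitions are not eligible.
            if np.bincount(labels).min() >= 2:
                eligible.append(k)
        if not labelings:
            raise ConsensusError("no valid consensus partition in scan range")
        pool = eligible if eligible else sorted(labelings)
        db_best = min(db_trace[k] for k in pool)
        near = [k for k in pool
                if db_trace[k] <= db_best * (1.0 + self.db_tie_tolerance)]
        k_star = max(near, key=lambda k: (sil_trace[k], -k))
        return labelings[k_star], k_star, db_trace, sil_trace

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.labels_
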