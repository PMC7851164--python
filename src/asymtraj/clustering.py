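"""Clustering of asymmetry age trajectories.

Significant vertices are clustered by the shape of their demeaned LH-RH
age trajectories: the dissimilarity between two vertices is the sum over
grid ages of squared trajectory differences ("sum of least squares"), the
partition is found by partitioning around medoids (PAM, BUILD + SWAP), and
the number of clusters is chosen by the mean silhouette width over a range
of candidate K (default 2-7).

Because trajectories are demeaned (no intercept), the mean LH-RH offset of
a vertex does not influence the clustering — only the shape of change does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_samples

from .vertexwise import AsymmetryTrajectorySet


def compute_dissimilarity(
    trajs: AsymmetryTrajectorySet, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise sum-of-squared-differences between vertex trajectories.

    Returns ``(D, vertex_ids)`` where D[i, j] = sum_g (d_i(a_g) - d_j(a_g))^2
    over the shared age grid, for the vertices selected by ``mask`` (all if
    None).
    """
    T = trajs.trajectories
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape[0] != T.shape[0]:
            raise ValueError("mask length does not match trajectory set")
        ids = np.flatnonzero(mask)
    else:
        ids = np.arange(T.shape[0])
    if ids.size == 0:
        raise ValueError("mask selects no vertices")
    X = T[ids]
    bad = ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite trajectories at vertices {ids[bad].tolist()}"
        )
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D, ids


@dataclass
class Partition:
    """A K-medoid partition of the retained vertices."""

    labels: np.ndarray               # cluster id (1..K) per retained point
    medoids: np.ndarray              # indices (into retained set) of medoids
    vertex_ids: np.ndarray           # retained-vertex -> mesh-vertex map
    cost: float                      # total dissimilarity to medoids
    silhouette: np.ndarray | None = None
    mean_silhouette: float | None = None

    @property
    def K(self) -> int:
        return len(self.medoids)

    def labels_on_mesh(self, n_vertices: int) -> np.ndarray:
        """0 = not retained, 1..K = cluster, over the full mesh."""
        out = np.zeros(n_vertices, dtype=int)
        out[self.vertex_ids] = self.labels
        return out


class PAM:
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    Classical BUILD initialization (greedy cost-minimizing medoid choice)
    followed by SWAP passes: while any single medoid-for-non-medoid exchange
    reduces the total cost, perform the best such exchange.  Because the
    swap neighborhood has genuine local optima even on small instances, the
    search is additionally restarted from a fixed set of alternative first
    medoids (the points of lowest total dissimilarity), and the best
    converged solution is returned.  Fully deterministic given the matrix.
    Follows the scikit-learn estimator protocol with
    ``metric="precomputed"`` semantics.
    """

    def __init__(self, n_clusters: int = 3, max_swaps: int = 500,
                 n_restarts: int = 10):
        self.n_clusters = n_clusters
        self.max_swaps = max_swaps
        self.n_restarts = n_restarts

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "max_swaps": self.max_swaps,
                "n_restarts": self.n_restarts}

    def set_params(self, **params) -> "PAM":
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, D: np.ndarray) -> "PAM":
        D = np.asarray(D, float)
        n = D.shape[0]
        K = self.n_clusters
        if D.ndim != 2 or D.shape[1] != n:
            raise ValueError("D must be square")
        if not 2 <= K < n:
            raise ValueError(f"need 2 <= n_clusters < n_points, got K={K}, n={n}")

        total = D.sum(axis=1)
        starts = [int(np.argmin(total))]
        if self.n_restarts > 1:
            for s in np.argsort(total, kind="stable"):
                if int(s) not in starts:
                    starts.append(int(s))
                if len(starts) >= self.n_restarts:
                    break
        best = None
        for s in starts:
            medoids, trace = self._build_and_swap(D, K, first=s)
            cost = trace[-1]
            if best is None or cost < best[1] - 1e-12:
                best = (medoids, cost, trace)
        medoids, cost, trace = best
        Dm = D[medoids]
        self.medoid_indices_ = medoids.copy()
        self.labels_ = np.argmin(Dm, axis=0) + 1
        self.inertia_ = float(cost)
        self.cost_trace_ = trace
        return self

    def _build_and_swap(self, D, K, first):
        n = D.shape[0]
        # BUILD: greedy cost-minimizing additions after the given first medoid
        medoids = [first]
        dist_near = D[first].copy()
        for _ in range(1, K):
            gain = np.sum(np.maximum(dist_near[None, :] - D, 0.0), axis=1)
            gain[medoids] = -np.inf
            m = int(np.argmax(gain))
            medoids.append(m)
            dist_near = np.minimum(dist_near, D[m])
        cost_trace = [float(dist_near.sum())]
        medoids = np.array(medoids)
        for _ in range(self.max_swaps):
            Dm = D[medoids]                      # (K, n)
            order = np.argsort(Dm, axis=0)
            nearest = order[0]                   # medoid index (0..K-1) per point
            d1 = Dm[nearest, np.arange(n)]
            d2 = Dm[order[1], np.arange(n)]
            best_delta, best_swap = -1e-12, None
            for mi in range(K):
                served = nearest == mi
                # removing medoid mi re-routes its points to their second choice
                base = np.where(served, d2, d1)
                for h in range(n):
                    if h in medoids:
                        continue
                    delta = float(np.sum(np.minimum(base, D[h]) - d1))
                    if delta < best_delta:
                        best_delta, best_swap = delta, (mi, h)
            if best_swap is None:
                break
            mi, h = best_swap
            medoids[mi] = h
            cost_trace.append(float(D[medoids].min(axis=0).sum()))
        return medoids, cost_trace

    def fit_predict(self, D: np.ndarray) -> np.ndarray:
        return self.fit(D).labels_


def pam_cluster(D: np.ndarray, K: int,
                vertex_ids: np.ndarray | None = None) -> Partition:
    """PAM partition of a precomputed dissimilarity matrix."""
    est = PAM(n_clusters=K).fit(D)
    ids = (np.asarray(vertex_ids) if vertex_ids is not None
           else np.arange(D.shape[0]))
    return Partition(
        labels=est.labels_, medoids=est.medoid_indices_, vertex_ids=ids,
        cost=est.inertia_,
    )


def silhouette_widths(D: np.ndarray, labels: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Per-point and mean silhouette widths for a precomputed matrix.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean within-cluster
    dissimilarity and b_i the best neighboring cluster mean; singletons
    score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    D = np.asarray(D, float)
    widths = silhouette_samples(D, labels, metric="precomputed")
    return widths, float(widths.mean())


def _order_labels_by_intercept(
    partition: Partition, trajs: AsymmetryTrajectorySet
) -> Partition:
    """Renumber clusters by descending mean trajectory value at the youngest
    grid age, so cluster 1 is the most leftward-asymmetric-in-youth family."""
    T = trajs.trajectories[partition.vertex_ids]
    start_vals = {}
    for lab in np.unique(partition.labels):
        start_vals[lab] = float(T[partition.labels == lab, 0].mean())
    order = sorted(start_vals, key=lambda lab: -start_vals[lab])
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = np.array([remap[l] for l in partition.labels])
    med_order = np.argsort([remap[partition.labels[m]] for m in partition.medoids])
    return Partition(
        labels=new_labels,
        medoids=partition.medoids[med_order],
        vertex_ids=partition.vertex_ids,
        cost=partition.cost,
        silhouette=partition.silhouette,
        mean_silhouette=partition.mean_silhouette,
    )


def select_solution(
    D: np.ndarray,
    K_range: range | tuple = range(2, 8),
    vertex_ids: np.ndarray | None = None,
    trajs: AsymmetryTrajectorySet | None = None,
) -> tuple[Partition, list[dict]]:
    """Choose the partition maximizing mean silhouette width over K.

    Returns the best partition (ties broken toward smaller K) and a table
    of {K, mean_silhouette, cost} rows.  If ``trajs`` is given, cluster ids
    of the winning partition are renumbered by descending
    intercept-at-youngest-age for reproducible labeling.
    """
    n = D.shape[0]
    table, partitions = [], {}
    for K in K_range:
        if not 2 <= K < n:
            continue
        part = pam_cluster(D, K, vertex_ids)
        widths, mean_w = silhouette_widths(D, part.labels)
        part.silhouette = widths
        part.mean_silhouette = mean_w
        partitions[K] = part
        table.append({"K": K, "mean_silhouette": mean_w, "cost": part.cost})
    if not table:
        raise ValueError("no valid K in range for this matrix size")
    best_K = max(
        sorted(partitions), key=lambda K: (partitions[K].mean_silhouette, -K)
    )
    best = partitions[best_K]
    if trajs is not None:
        best = _order_labels_by_intercept(best, trajs)
    return best, table
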