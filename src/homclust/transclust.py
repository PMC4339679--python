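"""Transitivity clustering: minimum-cost edit of the threshold graph into
a disjoint union of cliques (weighted transitive graph projection, WTGPP).

Given a similarity threshold ``T``, the threshold graph connects pairs with
``s(i,j) > T``. A partition's edit cost charges ``T - s(i,j)`` for every
same-cluster pair that lacks a threshold edge (edge addition against weak
evidence) and ``s(i,j) - T`` for every cross-cluster pair that has one
(deletion of a strong edge). The optimum is NP-hard, so the pipeline runs a
CAST greedy construction, refines it by steepest-descent single-node moves,
optionally solves small instances exactly by set-partition enumeration, and
reports the lowest-cost candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import Clustering
from .similarity import SimilarityMatrix

DEFAULT_N_MAX_EXACT = 10


@dataclass
class CostedPartition:
    """A partition together with its recomputable edit cost and provenance."""

    clustering: Clustering
    cost: float
    method: str  # "cast" | "refined" | "exact"


def _dense(S: SimilarityMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(S, SimilarityMatrix):
        return S.toarray().astype(float), list(S.roster)
    A = np.asarray(S, dtype=float)
    return A.copy(), [str(i) for i in range(A.shape[0])]


def _link_matrix(A: np.ndarray, T: float) -> tuple[np.ndarray, float]:
    """Per-pair same-cluster cost terms plus the partition-independent base.

    cost(P) = base + sum over same-cluster pairs of m[i,j], where
    m[i,j] = (T - s) for missing threshold edges (s <= T) and -(s - T) for
    present ones, and base = total deletion cost if every edge were cut.
    """
    M = np.where(A <= T, T - A, -(A - T))
    np.fill_diagonal(M, 0.0)
    base = float(np.triu(np.where(A > T, A - T, 0.0), k=1).sum())
    return M, base


def _cost_from_labels(A: np.ndarray, T: float, labels: np.ndarray) -> float:
    M, base = _link_matrix(A, T)
    same = labels[:, None] == labels[None, :]
    return float(max(base + M[same].sum() / 2.0, 0.0))


def clustering_cost(S: SimilarityMatrix | np.ndarray, T: float, partition: Clustering) -> float:
    """Edit cost of ``partition`` against the threshold graph at ``T``.

    Zero iff the threshold graph is already the disjoint clique union the
    partition describes.
    """
    A, roster = _dense(S)
    part_roster = partition.roster
    if sorted(part_roster) != sorted(roster):
        raise ValueError("partition must cover the similarity matrix roster exactly")
    pos = {p: i for i, p in enumerate(roster)}
    labels = np.empty(len(roster), dtype=int)
    for cid, cluster in enumerate(partition.clusters):
        for p in cluster:
            labels[pos[p]] = cid
    return _cost_from_labels(A, T, labels)


def cast_greedy(S: SimilarityMatrix | np.ndarray, T: float) -> CostedPartition:
    """CAST (Cluster Affinity Search Technique) greedy construction.

    Opens a cluster at the unassigned node with the most threshold-graph
    neighbors, alternately adds the unassigned node with highest average
    similarity to the cluster (when that average exceeds ``T``) and evicts
    members whose average similarity to the rest drops to ``T`` or below,
    closing the cluster when stable.
    """
    A, roster = _dense(S)
    n = len(roster)
    adj = A > T
    unassigned = set(range(n))
    clusters: list[list[int]] = []
    while unassigned:
        seed = max(unassigned, key=lambda i: (int(adj[i, list(unassigned)].sum()), -i))
        cluster = [seed]
        unassigned.discard(seed)
        changed = True
        guard = 0
        while changed and guard < 4 * n + 8:
            guard += 1
            changed = False
            # add phase
            while unassigned:
                members = np.array(cluster)
                cands = list(unassigned)
                avg = A[np.ix_(cands, members)].mean(axis=1)
                k = int(np.argmax(avg))
                if avg[k] > T:
                    cluster.append(cands[k])
                    unassigned.discard(cands[k])
                    changed = True
                else:
                    break
            # removal phase
            while len(cluster) > 1:
                members = np.array(cluster)
                sums = A[np.ix_(members, members)].sum(axis=1)
                avg_rest = sums / (len(cluster) - 1)
                k = int(np.argmin(avg_rest))
                if avg_rest[k] <= T:
                    evicted = cluster.pop(k)
                    unassigned.add(evicted)
                    changed = True
                else:
                    break
        clusters.append(sorted(cluster))
    labels = np.empty(n, dtype=int)
    for cid, cl in enumerate(clusters):
        labels[cl] = cid
    clustering = Clustering.from_labels(roster, labels)
    return CostedPartition(clustering, _cost_from_labels(A, T, labels), "cast")


def refine_partition(S: SimilarityMatrix | np.ndarray, T: float, start: Clustering,
                     max_rounds: int = 100) -> CostedPartition:
    """Steepest-descent single-node moves from ``start``.

    Each pass scans nodes in roster order; a node takes the move (to any
    other cluster or to a fresh singleton) with the largest strict cost
    decrease. Stops when a full pass makes no move or after ``max_rounds``.
    The result never costs more than the start.
    """
    A, roster = _dense(S)
    n = len(roster)
    pos = {p: i for i, p in enumerate(roster)}
    M, base = _link_matrix(A, T)
    labels = np.empty(n, dtype=int)
    for cid, cl in enumerate(start.clusters):
        for p in cl:
            labels[pos[p]] = cid
    next_label = int(labels.max(initial=-1)) + 1
    for _ in range(max_rounds):
        moved = False
        for v in range(n):
            cur = labels[v]
            # cost contribution of v toward each cluster
            gains = np.zeros(next_label + 1)
            np.add.at(gains, labels, M[v])
            attach_cur = gains[cur] - M[v, v]  # M diag is 0, kept for clarity
            # candidate: every existing cluster + a fresh singleton (index next_label)
            deltas = gains - attach_cur
            deltas[cur] = 0.0
            best = int(np.argmin(deltas))
            if deltas[best] < -1e-12:
                labels[v] = best
                if best == next_label:
                    next_label += 1
                moved = True
        if not moved:
            break
    clustering = Clustering.from_labels(roster, labels)
    return CostedPartition(clustering, _cost_from_labels(A, T, labels), "refined")


def _partitions_rgs(n: int):
    """Yield set partitions of range(n) as restricted-growth label arrays,
    in lexicographic order."""
    labels = [0] * n

    def rec(i: int, m: int):
        if i == n:
            yield list(labels)
            return
        for l in range(m + 1):
            labels[i] = l
            yield from rec(i + 1, max(m, l + 1))

    yield from rec(1, 1) if n > 0 else iter([[]])


def exact_partition(S: SimilarityMatrix | np.ndarray, T: float,
                    n_max: int = DEFAULT_N_MAX_EXACT) -> CostedPartition:
    """Globally optimal partition by exhaustive set-partition enumeration.

    Intended as an oracle and as the exact branch for tiny instances; raises
    for rosters larger than ``n_max`` (Bell numbers explode quickly).
    Ties are broken toward the lexicographically smallest restricted-growth
    encoding, which the enumeration order provides for free.
    """
    A, roster = _dense(S)
    n = len(roster)
    if n > n_max:
        raise ValueError(
            f"roster size {n} exceeds n_max={n_max}; use cast_greedy/refine_partition instead"
        )
    if n == 0:
        return CostedPartition(Clustering([]), 0.0, "exact")
    M, base = _link_matrix(A, T)
    best_cost = np.inf
    best_labels: list[int] | None = None
    for labels in _partitions_rgs(n):
        arr = np.asarray(labels)
        intra = 0.0
        for i in range(n):
            intra += M[i, arr == arr[i]].sum() - M[i, i]
        cost = base + intra / 2.0
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_labels = labels
    clustering = Clustering.from_labels(roster, best_labels)  # type: ignore[arg-type]
    return CostedPartition(clustering, float(max(best_cost, 0.0)), "exact")


class TransitivityClustering(BaseEstimator, ClusterMixin):
    """Transitivity clusterer over a precomputed similarity matrix.

    Runs CAST, refines it, adds the exact solution when the instance has at
    most ``n_max_exact`` nodes, and keeps the cheapest candidate.

    Attributes
    ----------
    labels_ : dense integer cluster ids in roster order.
    clusters_ : the winning :class:`Clustering`.
    cost_ : its edit cost.
    method_ : which candidate won ("cast", "refined" or "exact").
    """

    def __init__(self, threshold: float = 0.0, n_max_exact: int = DEFAULT_N_MAX_EXACT,
                 max_rounds: int = 100):
        self.threshold = threshold
        self.n_max_exact = n_max_exact
        self.max_rounds = max_rounds

    def fit(self, X: SimilarityMatrix | np.ndarray, y=None) -> "TransitivityClustering":
        A, roster = _dense(X)
        if len(roster) == 0:
            self.clusters_ = Clustering([])
            self.labels_ = np.array([], dtype=int)
            self.cost_ = 0.0
            self.method_ = "exact"
            return self
        cast = cast_greedy(X, self.threshold)
        refined = refine_partition(X, self.threshold, cast.clustering, self.max_rounds)
        candidates = [cast, refined]
        if len(roster) <= self.n_max_exact:
            candidates.append(exact_partition(X, self.threshold, self.n_max_exact))
        winner = min(candidates, key=lambda c: c.cost)
        labels = winner.clustering.labels_for(roster)
        self.clusters_ = Clustering.from_labels(roster, labels, {"cost": winner.cost, "method": winner.method})
        self.labels_ = np.asarray(labels, dtype=int)
        self.cost_ = winner.cost
        self.method_ = winner.method
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def transclust_cluster(S: SimilarityMatrix | np.ndarray, T: float,
                       n_max_exact: int = DEFAULT_N_MAX_EXACT) -> CostedPartition:
    """Functional wrapper: lowest-cost candidate among CAST, refined, exact."""
    est = TransitivityClustering(T, n_max_exact).fit(S)
    return CostedPartition(est.clusters_, est.cost_, est.method_)
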