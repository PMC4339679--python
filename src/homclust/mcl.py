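"""Markov clustering (MCL) of a similarity matrix.

MCL simulates flow on the similarity graph: similarities are turned into a
column-stochastic transition matrix, then expansion (matrix squaring, which
spreads flow along longer paths) alternates with inflation (entrywise power
``I`` followed by column renormalization, which sharpens strong transitions
and starves weak ones) until the matrix stops changing. The limit matrix is
nearly idempotent and its nonzero pattern decomposes the graph into attractor
systems, read out as clusters. Inflation controls granularity: larger ``I``
yields more, smaller clusters.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import Clustering
from .similarity import SimilarityMatrix

_ATTRACTOR_TOL = 1e-7


def _as_dense(S: SimilarityMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(S, SimilarityMatrix):
        return S.toarray().astype(float), list(S.roster)
    A = np.asarray(S, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("similarity input must be a square matrix")
    return A.copy(), [str(i) for i in range(A.shape[0])]


def make_stochastic(S: SimilarityMatrix | np.ndarray, self_loop: float | str = "auto") -> np.ndarray:
    """Column-stochastic transition matrix from similarities.

    ``self_loop="auto"`` adds, per node, a loop equal to its maximum incident
    similarity (standard MCL practice; damps period-2 oscillation). A node
    whose column would be all-zero receives an implicit unit self-loop so
    every column sums to 1.
    """
    A, _ = _as_dense(S)
    if A.size == 0:
        return A
    np.fill_diagonal(A, 0.0)
    if self_loop == "auto":
        loops = A.max(axis=0)
        loops[loops <= 0] = 1.0
    else:
        w = float(self_loop)
        if w < 0:
            raise ValueError("self_loop must be non-negative")
        loops = np.full(A.shape[0], w)
    A[np.diag_indices_from(A)] = loops
    colsum = A.sum(axis=0)
    dead = colsum <= 0
    if dead.any():
        A[np.where(dead)[0], np.where(dead)[0]] = 1.0
        colsum = A.sum(axis=0)
    return A / colsum


def _inflate(M: np.ndarray, inflation: float, prune_tol: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        P = np.power(M, inflation, where=M > 0, out=np.zeros_like(M))
    if prune_tol > 0:
        pruned = np.where(P < prune_tol, 0.0, P)
        # never let pruning empty a column: restore its largest pre-prune entry
        dead = pruned.sum(axis=0) <= 0
        if dead.any():
            for j in np.where(dead)[0]:
                pruned[np.argmax(P[:, j]), j] = P[:, j].max() if P[:, j].max() > 0 else 1.0
        P = pruned
    return P / P.sum(axis=0)


def mcl_step(M: np.ndarray, inflation: float = 2.0, prune_tol: float = 1e-8) -> np.ndarray:
    """One MCL iteration: expansion (``M @ M``) then inflation."""
    return _inflate(M @ M, inflation, prune_tol)


def _extract_clusters(M: np.ndarray) -> list[int]:
    """Clusters from the (near-)limit matrix.

    Attractors are rows with positive diagonal mass; attractor systems are
    the weakly connected components of the nonzero pattern restricted to
    attractor rows. Every other node joins the system of the attractor
    holding the largest share of its column (ties: smallest attractor
    index in roster order).
    """
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > _ATTRACTOR_TOL]
    if not attractors:
        # degenerate (non-converged) matrix: treat each column's argmax row
        # as that node's attractor
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))
    # union attractors that pull on each other or share a column
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    att_set = set(attractors)
    for j in range(n):
        pullers = [i for i in attractors if M[i, j] > _ATTRACTOR_TOL]
        if j in att_set:
            for i in pullers:
                union(i, j)
    labels = [-1] * n
    for j in range(n):
        if j in att_set:
            labels[j] = find(j)
            continue
        pullers = [i for i in attractors if M[i, j] > _ATTRACTOR_TOL]
        if pullers:
            best = max(pullers, key=lambda i: (M[i, j], -i))
            labels[j] = find(best)
        else:
            labels[j] = j  # orphan: its own singleton
    return labels


class MarkovClustering(BaseEstimator, ClusterMixin):
    """MCL clusterer over a precomputed similarity matrix.

    Parameters
    ----------
    inflation : float, default 2.0
        Entrywise power of the inflation operator. Values > 1 sharpen flow
        (the classical regime); values ≤ 1 are accepted but flatten flow and
        typically give one giant cluster — supported for parameter sweeps,
        outside the classical regime.
    self_loop : float or "auto", default "auto"
        Diagonal weight added before normalization; "auto" uses each node's
        maximum incident similarity.
    prune_tol : float
        Entries below this are zeroed during inflation (with a guard that
        never empties a column).
    max_iter, conv_tol
        Iteration stops when the largest entry change falls below
        ``conv_tol`` or after ``max_iter`` steps (then ``converged_`` is
        False and the current matrix is read out anyway).

    Attributes
    ----------
    labels_ : ndarray of dense cluster ids, aligned with the input roster.
    clusters_ : the resulting :class:`Clustering`.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, inflation: float = 2.0, self_loop: float | str = "auto",
                 prune_tol: float = 1e-8, max_iter: int = 200, conv_tol: float = 1e-6):
        self.inflation = inflation
        self.self_loop = self_loop
        self.prune_tol = prune_tol
        self.max_iter = max_iter
        self.conv_tol = conv_tol

    def fit(self, X: SimilarityMatrix | np.ndarray, y=None) -> "MarkovClustering":
        if self.inflation <= 0:
            raise ValueError("inflation must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        A, roster = _as_dense(X)
        if A.shape[0] == 0:
            self.labels_ = np.array([], dtype=int)
            self.clusters_ = Clustering([], {"converged": True, "n_iter": 0})
            self.converged_ = True
            self.n_iter_ = 0
            return self
        M = make_stochastic(A, self.self_loop)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            M_next = mcl_step(M, self.inflation, self.prune_tol)
            if np.max(np.abs(M_next - M)) < self.conv_tol:
                M = M_next
                converged = True
                break
            M = M_next
        raw = _extract_clusters(M)
        self.clusters_ = Clustering.from_labels(roster, raw, {"converged": converged, "n_iter": it})
        self.labels_ = np.asarray(self.clusters_.labels_for(roster), dtype=int)
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def mcl_cluster(S: SimilarityMatrix, inflation: float = 2.0, self_loop: float | str = "auto",
                prune_tol: float = 1e-8, max_iter: int = 200, conv_tol: float = 1e-6) -> Clustering:
    """Functional wrapper around :class:`MarkovClustering`."""
    est = MarkovClustering(inflation, self_loop, prune_tol, max_iter, conv_tol).fit(S)
    return est.clusters_
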