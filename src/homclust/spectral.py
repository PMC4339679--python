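"""SCPS-style spectral clustering of a protein similarity matrix.

The pipeline first peels off tiny connected components (fewer than five
proteins by default) as finished clusters — flow-based splitting cannot
improve them — then builds the normalized affinity operator
``L = D^{-1/2} S' D^{-1/2}`` on the remainder, where ``S'`` is the
similarity matrix scaled by its global maximum and ``d_ii = sum_j s'_ij``.
Rows of the matrix of the top-``K`` eigenvectors of ``L``, rescaled to unit
Euclidean norm, embed each protein as a point on the unit sphere in R^K;
K-means groups the points. With ``K`` unset it is chosen at the largest
eigengap ``lambda_k - lambda_{k+1}``: for a graph with m well-separated
blocks the eigenvalue 1 has multiplicity m, so the gap sits at k = m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .containers import Clustering
from .similarity import SimilarityMatrix

DEFAULT_MIN_COMPONENT = 5


@dataclass
class SpectralEmbedding:
    """Top-K eigenvector embedding of the normalized affinity operator."""

    U: np.ndarray              # (n_retained, K), rows unit-norm
    eigenvalues: np.ndarray    # all eigenvalues of L, non-increasing
    K: int
    roster: list[str]

    def __post_init__(self) -> None:
        if self.U.shape[1] != self.K:
            raise ValueError("U must have exactly K columns")


def _as_simmatrix(S: SimilarityMatrix | np.ndarray) -> SimilarityMatrix:
    if isinstance(S, SimilarityMatrix):
        return S
    return SimilarityMatrix.from_dense(np.asarray(S, dtype=float))


def peel_small_components(S: SimilarityMatrix | np.ndarray,
                          min_size: int = DEFAULT_MIN_COMPONENT
                          ) -> tuple[list[list[str]], SimilarityMatrix]:
    """Split off connected components smaller than ``min_size`` as final
    clusters; return them plus the reduced matrix of the remaining nodes."""
    if min_size < 1:
        raise ValueError("min_size must be ≥ 1")
    S = _as_simmatrix(S)
    n_comp, comp = S.connected_components()
    sizes = np.bincount(comp, minlength=n_comp)
    small: list[list[str]] = []
    keep: list[int] = []
    for c in range(n_comp):
        members = np.where(comp == c)[0]
        if sizes[c] < min_size:
            small.append([S.roster[i] for i in members])
        else:
            keep.extend(members.tolist())
    keep.sort()
    return small, S.submatrix(keep)


def build_embedding(S_reduced: SimilarityMatrix | np.ndarray, K: int | str = "auto") -> SpectralEmbedding:
    """Normalized-affinity eigenvector embedding with unit-norm rows.

    ``K="auto"`` picks the largest eigengap over k in [1, n/2] (bounded to
    avoid degenerate, near-singleton K).
    """
    S_reduced = _as_simmatrix(S_reduced)
    n = S_reduced.n
    if n == 0:
        raise ValueError("cannot embed an empty similarity matrix")
    A = S_reduced.toarray()
    mx = A.max()
    if mx <= 0:
        raise ValueError("similarity matrix has no positive entries to embed")
    Sp = A / mx
    d = Sp.sum(axis=1)
    if np.any(d <= 0):
        bad = [S_reduced.roster[i] for i in np.where(d <= 0)[0]]
        raise ValueError(f"zero-degree nodes reached the spectral stage: {bad}; peel them first")
    dinv = 1.0 / np.sqrt(d)
    L = dinv[:, None] * Sp * dinv[None, :]
    try:
        eigvals, eigvecs = np.linalg.eigh((L + L.T) / 2.0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical failure path
        raise ArithmeticError(
            f"eigendecomposition failed for {n}x{n} operator "
            f"(max |L| {np.abs(L).max():.3g}, degree range [{d.min():.3g}, {d.max():.3g}])"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if K == "auto":
        k_chosen = choose_k_by_eigengap(eigvals, n)
    else:
        k_chosen = int(K)
        if not (1 <= k_chosen <= n):
            raise ValueError(f"K={k_chosen} outside [1, {n}]")
    U = eigvecs[:, :k_chosen].copy()
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    U = U / norms[:, None]
    return SpectralEmbedding(U, eigvals, k_chosen, list(S_reduced.roster))


def choose_k_by_eigengap(eigenvalues: np.ndarray, n: int) -> int:
    """K at the largest gap λ_k − λ_{k+1}, searching k in [1, max(1, n // 2)]."""
    if n <= 1:
        return 1
    kmax = max(1, n // 2)
    kmax = min(kmax, len(eigenvalues) - 1)
    if kmax < 1:
        return 1
    gaps = eigenvalues[:kmax] - eigenvalues[1 : kmax + 1]
    return int(np.argmax(gaps)) + 1


def kmeans_assign(embedding: SpectralEmbedding, K: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means (k-means++ seeding, ``n_init`` restarts, best inertia kept)
    over the embedded points; deterministic given ``seed``."""
    n = embedding.U.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of embedded points {n}")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return km.fit_predict(embedding.U)


class SCPSClustering(BaseEstimator, ClusterMixin):
    """Spectral clusterer over a precomputed similarity matrix.

    Parameters
    ----------
    n_clusters : int or "auto"
        Cluster count for the spectral stage (the peeled components come on
        top); "auto" uses the eigengap rule.
    min_component_size : int, default 5
        Components smaller than this bypass the spectral stage.
    n_init : int
        K-means restarts.
    random_state : int
        Seed for the K-means restarts.

    Attributes
    ----------
    labels_, clusters_ : resulting partition over the full roster.
    k_ : spectral-stage cluster count actually used (0 if everything peeled).
    eigenvalues_ : spectrum of the normalized operator (empty if peeled).
    """

    def __init__(self, n_clusters: int | str = "auto", min_component_size: int = DEFAULT_MIN_COMPONENT,
                 n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.min_component_size = min_component_size
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: SimilarityMatrix | np.ndarray, y=None) -> "SCPSClustering":
        S = _as_simmatrix(X)
        roster = list(S.roster)
        small, reduced = peel_small_components(S, self.min_component_size)
        clusters: list[list[str]] = [list(c) for c in small]
        if reduced.n == 0:
            if self.n_clusters != "auto":
                import warnings

                warnings.warn("requested cluster count ignored: all components were peeled")
            self.k_ = 0
            self.eigenvalues_ = np.array([])
        else:
            K = self.n_clusters
            if K != "auto":
                K = min(int(K), reduced.n)
            emb = build_embedding(reduced, K)
            assign = kmeans_assign(emb, emb.K, self.random_state, self.n_init)
            for k in range(emb.K):
                members = [emb.roster[i] for i in np.where(assign == k)[0]]
                if members:
                    clusters.append(members)
            self.k_ = emb.K
            self.eigenvalues_ = emb.eigenvalues
        self.clusters_ = Clustering.from_labels(
            roster,
            Clustering(clusters).labels_for(roster),
            {"k": self.k_, "n_peeled": len(small)},
        )
        self.labels_ = np.asarray(self.clusters_.labels_for(roster), dtype=int)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def scps_cluster(S: SimilarityMatrix | np.ndarray, c: int | str = "auto", seed: int = 0,
                 min_component_size: int = DEFAULT_MIN_COMPONENT, n_init: int = 10) -> Clustering:
    """Functional wrapper around :class:`SCPSClustering` (``c`` = cluster
    count for the spectral stage, or "auto")."""
    est = SCPSClustering(c, min_component_size, n_init, seed).fit(S)
    return est.clusters_
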