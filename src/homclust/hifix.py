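"""HiFix-lite: hierarchical family refinement of a similarity network.

Three stages mirror the high-fidelity clustering pipeline for protein
families:

1. *Pre-families*: a low-stringency connected-component pass keeps edges
   whose fractional identity exceeds ``s_min`` and alignment coverage
   exceeds ``c_min``; components are large, permissive candidate families.
2. *Communities*: each pre-family graph is decomposed by Louvain modularity
   optimization (seeded, hence reproducible) into homogeneous communities.
3. *Merging*: communities are progressively merged, always joining the pair
   with the highest inter-connectivity ``pi_ql`` (realized edges between q
   and l divided by |q|*|l| possible ones), until one cluster remains; the
   partition with the highest modularity along the trajectory — the initial
   partition included — is kept. Modularity here stands in for the original
   model-based (pHMM/ICL) cluster-quality criterion, which needs alignment
   machinery outside this package's scope.

Edges are weighted by the ``-log10`` e-value similarity score when it is
positive, else by 1, so stronger homology pulls communities together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import Clustering
from .similarity import SearchHit, evalue_to_score


@dataclass
class PreFamilyGraph:
    """One low-stringency connected component with its weighted edge graph."""

    graph: nx.Graph
    s_min: float
    c_min: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class CommunitySet:
    """A partition of one pre-family into communities, with modularity and
    the pairwise connectivity table pi[q][l]."""

    communities: list[list[str]]
    modularity: float
    pi: dict[tuple[int, int], float] = field(default_factory=dict)


def _edge_weight(hit: SearchHit) -> float:
    s = evalue_to_score(hit.evalue)
    return s if s > 0 else 1.0


def connected_prefamilies(hits: Sequence[SearchHit], s_min: float, c_min: float) -> list[PreFamilyGraph]:
    """Low-stringency connected components of the identity/coverage-filtered
    hit graph.

    ``s_min`` is fractional identity in [0, 1] (compared against
    ``percent_identity / 100``); ``c_min`` is coverage in [0, 1]. Hits
    without a coverage value pass the coverage test only when ``c_min`` is 0;
    hits without identity are skipped as edges. Isolated proteins come back
    as singleton pre-families.
    """
    for name, v in (("s_min", s_min), ("c_min", c_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    G = nx.Graph()
    for h in hits:
        G.add_node(h.query_id)
        G.add_node(h.subject_id)
        if h.query_id == h.subject_id:
            continue
        if h.percent_identity is None or h.percent_identity / 100.0 <= s_min:
            continue
        if h.alignment_coverage is None:
            if c_min > 0:
                continue
        elif h.alignment_coverage <= c_min:
            continue
        w = _edge_weight(h)
        if G.has_edge(h.query_id, h.subject_id):
            G[h.query_id][h.subject_id]["weight"] = max(G[h.query_id][h.subject_id]["weight"], w)
        else:
            G.add_edge(h.query_id, h.subject_id, weight=w)
    return [PreFamilyGraph(G.subgraph(c).copy(), s_min, c_min) for c in nx.connected_components(G)]


def _modularity(graph: nx.Graph, communities: list[list[str]]) -> float:
    """Weighted modularity Q = sum_c (w_c / w - (d_c / 2w)^2)."""
    w = graph.size(weight="weight")
    if w <= 0:
        return 0.0
    q = 0.0
    for comm in communities:
        members = set(comm)
        w_c = sum(d["weight"] for u, v, d in graph.edges(members, data=True) if v in members and u in members)
        d_c = sum(dict(graph.degree(members, weight="weight")).values())
        q += w_c / w - (d_c / (2 * w)) ** 2
    return q


def _dense_adjacency(G: nx.Graph) -> tuple[list[str], np.ndarray]:
    nodes = list(G.nodes)
    pos = {p: i for i, p in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, d in G.edges(data=True):
        W[pos[u], pos[v]] = W[pos[v], pos[u]] = d.get("weight", 1.0)
    return nodes, W


def _k_to_table(W: np.ndarray, k: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_comm = int(labels.max()) + 1
    k_to = np.zeros((W.shape[0], n_comm + 1))
    for c in range(n_comm):
        k_to[:, c] = W[:, labels == c].sum(axis=1)
    d_c = np.bincount(labels, weights=k, minlength=n_comm + 1)
    return k_to, d_c


def _move_passes(W: np.ndarray, k: np.ndarray, w: float, labels: np.ndarray,
                 max_passes: int = 50) -> np.ndarray:
    """Greedy single-node modularity moves, applied immediately, until a
    full pass changes nothing (the flat-graph Louvain phase-1 sweep)."""
    n = W.shape[0]
    for _ in range(max_passes):
        moved = False
        k_to, d_c = _k_to_table(W, k, labels)
        for v in range(n):
            a = labels[v]
            gain = (k_to[v] - k_to[v, a]) / w - k[v] * (d_c - d_c[a] + k[v]) / (2 * w * w)
            gain[a] = 0.0
            t = int(np.argmax(gain))
            if gain[t] > 1e-12:
                # apply and update the incremental tables
                k_to[:, t] += W[:, v]
                k_to[:, a] -= W[:, v]
                d_c[t] += k[v]
                d_c[a] -= k[v]
                labels[v] = t if t < k_to.shape[1] - 1 else t
                if t == k_to.shape[1] - 1:  # opened a fresh community
                    k_to = np.hstack([k_to, np.zeros((n, 1))])
                    d_c = np.append(d_c, 0.0)
                moved = True
        _, labels = np.unique(labels, return_inverse=True)
        if not moved:
            break
    return labels


def _refine_moves_and_swaps(G: nx.Graph, communities: list[list[str]], max_ops: int = 200) -> list[list[str]]:
    """Greedy modularity ascent by single-node moves and pairwise swaps.

    Node-move schemes stall in local optima that a two-node exchange
    escapes; this refinement runs fast move passes to a move-local optimum,
    then repeatedly applies the single best cross-community swap (deltas in
    closed form over a dense adjacency) followed by fresh move passes, until
    no operation raises Q.
    """
    nodes, W = _dense_adjacency(G)
    n = len(nodes)
    w = W.sum() / 2.0
    if w <= 0 or n < 2:
        return communities
    pos = {p: i for i, p in enumerate(nodes)}
    labels = np.empty(n, dtype=int)
    for c, comm in enumerate(communities):
        for p in comm:
            labels[pos[p]] = c
    k = W.sum(axis=1)
    labels = _move_passes(W, k, w, labels)
    for _ in range(max_ops):
        k_to, d_c = _k_to_table(W, k, labels)
        best_gain, best_pair = 1e-12, None
        for u in range(n):
            a = labels[u]
            d1 = (k_to[u, labels] - k_to[u, a]) / w - k[u] * (d_c[labels] - d_c[a] + k[u]) / (2 * w * w)
            d2 = ((k_to[:, a] - W[u]) - (k_to[np.arange(n), labels] + W[u])) / w \
                - k * ((d_c[a] - k[u]) - (d_c[labels] + k[u]) + k) / (2 * w * w)
            gain = d1 + d2
            gain[labels == a] = 0.0
            gain[: u + 1] = np.minimum(gain[: u + 1], 0.0)  # consider each unordered pair once
            v = int(np.argmax(gain))
            if gain[v] > best_gain:
                best_gain, best_pair = gain[v], (u, v)
        if best_pair is None:
            break
        u, v = best_pair
        labels[u], labels[v] = labels[v], labels[u]
        labels = _move_passes(W, k, w, labels)
    out: dict[int, list[str]] = {}
    for i, v in enumerate(nodes):
        out.setdefault(int(labels[i]), []).append(v)
    return [sorted(c) for c in out.values()]


def louvain_communities(graph: PreFamilyGraph | nx.Graph, seed: int = 0,
                        n_restarts: int = 3, n_random_starts: int = 8) -> CommunitySet:
    """Multi-start Louvain community detection on the pre-family graph.

    Louvain's greedy node sweeps are order-sensitive local optimizers, so
    the search is run from ``n_restarts`` seeded Louvain starts plus
    ``n_random_starts`` random initial partitions, each polished by a
    move-and-swap refinement (:func:`_refine_moves_and_swaps`); the
    highest-modularity partition wins. Deterministic given ``seed``.
    Returns the partition with its weighted modularity and the full pi_ql
    connectivity table.
    """
    G = graph.graph if isinstance(graph, PreFamilyGraph) else graph
    if G.number_of_nodes() == 0:
        raise ValueError("cannot decompose an empty graph")
    if G.number_of_edges() == 0:
        comms = [[n] for n in G.nodes]
    else:
        rng = np.random.default_rng(np.random.SeedSequence([max(seed, 0), 0x10F1]))
        nodes = list(G.nodes)
        candidates: list[list[list[str]]] = []
        for _ in range(max(1, n_restarts)):
            child = int(rng.integers(2**31 - 1))
            candidates.append(
                [sorted(c) for c in nx.community.louvain_communities(G, weight="weight", seed=child)]
            )
        for _ in range(n_random_starts):
            n_comm = int(rng.integers(1, max(2, len(nodes) // 2) + 1))
            labels = rng.integers(0, n_comm, len(nodes))
            groups: dict[int, list[str]] = {}
            for node, l in zip(nodes, labels):
                groups.setdefault(int(l), []).append(node)
            candidates.append([sorted(c) for c in groups.values()])
        best: list[list[str]] | None = None
        best_q = -np.inf
        for cand in candidates:
            refined = _refine_moves_and_swaps(G, cand)
            q = _modularity(G, refined)
            if q > best_q + 1e-15:
                best_q = q
                best = refined
        comms = sorted(best, key=lambda c: c[0])  # type: ignore[arg-type]
    cs = CommunitySet(comms, _modularity(G, comms))
    cs.pi = inter_connectivity(cs, graph)
    return cs


def inter_connectivity(communities: CommunitySet, graph: PreFamilyGraph | nx.Graph) -> dict[tuple[int, int], float]:
    """pi_ql = existing q–l edges / (|q| * |l|), symmetric, 0 without edges."""
    G = graph.graph if isinstance(graph, PreFamilyGraph) else graph
    comms = communities.communities
    member_of: dict[str, int] = {}
    for i, c in enumerate(comms):
        for p in c:
            member_of[p] = i
    counts: dict[tuple[int, int], int] = {}
    for u, v in G.edges:
        cu, cv = member_of[u], member_of[v]
        if cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        counts[key] = counts.get(key, 0) + 1
    pi: dict[tuple[int, int], float] = {}
    for q in range(len(comms)):
        for l in range(q + 1, len(comms)):
            val = counts.get((q, l), 0) / (len(comms[q]) * len(comms[l]))
            pi[(q, l)] = pi[(l, q)] = val
    return pi


def merge_by_connectivity(communities: CommunitySet, graph: PreFamilyGraph | nx.Graph) -> Clustering:
    """Progressive highest-pi_ql merging with modularity-based selection.

    Repeatedly merges the community pair with maximal pi_ql (ties: larger
    combined size, then lexicographically smallest first member),
    recomputing pi after each merge and recording modularity at every step;
    returns the partition with maximal modularity seen along the
    trajectory, the initial partition included.
    """
    G = graph.graph if isinstance(graph, PreFamilyGraph) else graph
    current = [list(c) for c in communities.communities]
    best = [list(c) for c in current]
    best_q = _modularity(G, current)
    while len(current) > 1:
        cs = CommunitySet(current, 0.0)
        pi = inter_connectivity(cs, G)
        best_pair = None
        for q in range(len(current)):
            for l in range(q + 1, len(current)):
                size = len(current[q]) + len(current[l])
                name = min(current[q][0], current[l][0])
                cand = (pi[(q, l)], size, name)
                if best_pair is None:
                    best_pair = (cand, (q, l))
                else:
                    (bpi, bsize, bname), _ = best_pair
                    if cand[0] > bpi or (cand[0] == bpi and (size > bsize or (size == bsize and name < bname))):
                        best_pair = (cand, (q, l))
        q_idx, l_idx = best_pair[1]
        merged = sorted(current[q_idx] + current[l_idx])
        current = [c for i, c in enumerate(current) if i not in (q_idx, l_idx)] + [merged]
        q_val = _modularity(G, current)
        if q_val > best_q + 1e-12:
            best_q = q_val
            best = [list(c) for c in current]
    return Clustering(sorted((sorted(c) for c in best), key=lambda c: c[0]))


class HiFixLite(BaseEstimator, ClusterMixin):
    """HiFix-style clusterer over raw search hits.

    ``fit`` accepts a sequence of :class:`SearchHit` (identity and coverage
    fields drive the pre-family stage). The final partition concatenates the
    refined communities of every pre-family.

    Attributes
    ----------
    labels_, clusters_ : final partition over all proteins seen in the hits.
    prefamilies_ : number of pre-families formed.
    trace_ : per-pre-family (n_nodes, n_communities, n_final_clusters).
    """

    def __init__(self, min_identity: float = 0.1, min_coverage: float = 0.0, random_state: int = 0):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.random_state = random_state

    def fit(self, X: Sequence[SearchHit], y=None) -> "HiFixLite":
        prefams = connected_prefamilies(X, self.min_identity, self.min_coverage)
        clusters: list[list[str]] = []
        trace = []
        for pf in prefams:
            if pf.graph.number_of_nodes() == 1:
                clusters.append(pf.nodes)
                trace.append((1, 1, 1))
                continue
            cs = louvain_communities(pf, self.random_state)
            merged = merge_by_connectivity(cs, pf)
            clusters.extend(merged.clusters)
            trace.append((pf.graph.number_of_nodes(), len(cs.communities), merged.n_clusters))
        roster = sorted({p for c in clusters for p in c})
        self.clusters_ = Clustering.from_labels(
            roster, Clustering(clusters).labels_for(roster), {"n_prefamilies": len(prefams)}
        )
        self.labels_ = self.clusters_.labels_for(roster)
        self.roster_ = roster
        self.prefamilies_ = len(prefams)
        self.trace_ = trace
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def hifix_cluster(hits: Sequence[SearchHit], s_min: float = 0.1, c_min: float = 0.0,
                  seed: int = 0) -> Clustering:
    """Functional wrapper around :class:`HiFixLite`."""
    return HiFixLite(s_min, c_min, seed).fit(hits).clusters_
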