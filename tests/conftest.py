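import numpy as np
import pytest

import homclust as hc


@pytest.fixture
def worked_gold():
    """Two size-2 families, the hand-enumerated evaluation fixture."""
    return hc.GoldStandard(
        {"a": "f1", "b": "f1", "c": "f2", "d": "f2"},
        {"a": "s1", "b": "s1", "c": "s2", "d": "s2"},
    )


@pytest.fixture
def worked_clustering():
    return hc.Clustering([["a", "b", "c"], ["d"]])


@pytest.fixture
def triangle_matrix():
    """3 nodes: strong a-b and a-c (score 10), weak b-c (score 1)."""
    A = np.array([[0.0, 10.0, 10.0], [10.0, 0.0, 1.0], [10.0, 1.0, 0.0]])
    return hc.SimilarityMatrix.from_dense(A, ["a", "b", "c"])


@pytest.fixture
def two_triangles():
    """Two unit-weight triangles joined by one weight-0.1 bridge (b2-c0)."""
    import networkx as nx

    G = nx.Graph()
    for tri in (["b0", "b1", "b2"], ["c0", "c1", "c2"]):
        for i in range(3):
            for j in range(i + 1, 3):
                G.add_edge(tri[i], tri[j], weight=1.0)
    G.add_edge("b2", "c0", weight=0.1)
    return G


def planted_matrix(rng, sizes, intra=10.0, inter=0.0, inter_density=0.0, noise=0.0):
    """Block similarity matrix with planted clusters; optional weak noise
    edges between blocks."""
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    blocks = []
    for s in sizes:
        blocks.append(list(range(start, start + s)))
        A[start:start + s, start:start + s] = intra
        start += s
    if inter_density > 0:
        for i in range(n):
            for j in range(i + 1, n):
                same = any(i in b and j in b for b in blocks)
                if not same and rng.uniform() < inter_density:
                    w = inter if noise == 0 else rng.uniform(0, noise)
                    A[i, j] = A[j, i] = w
    np.fill_diagonal(A, 0.0)
    return hc.SimilarityMatrix.from_dense(A), blocks
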