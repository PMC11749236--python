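import numpy as np
import pytest

from hiermap.graphio import EdgeTable, FeatureMatrix, LevelGraph, build_affinity_graph
from hiermap.treeops import Hierarchy


class UnionFind:
    """Independent union-find oracle for component checks."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return {min(v): v for v in out.values()}


@pytest.fixture
def union_find():
    return UnionFind


def make_graph(n, edges, dim=4, seed=0, channels=None):
    """Small level-0 graph with seeded features and given (u_idx, v_idx) edges."""
    rng = np.random.default_rng(seed)
    ids = tuple(f"n{i:02d}" for i in range(n))
    feats = rng.standard_normal((n, dim))
    e = np.array(sorted((min(a, b), max(a, b)) for a, b in edges), dtype=np.int64).reshape(-1, 2)
    if channels is None:
        attr = np.abs(rng.standard_normal((e.shape[0], 5)))
    else:
        attr = np.asarray(channels, dtype=float).reshape(-1, 5)
    return LevelGraph(level=0, node_ids=ids, node_features=feats, edges=e, edge_attr=attr)


@pytest.fixture
def graph_factory():
    return make_graph


@pytest.fixture
def toy_hierarchy():
    """root -> {s1 -> {g1, g2}, g3}"""
    return Hierarchy(
        genes=("g1", "g2", "g3"),
        children={"root": ["s1", "g3"], "s1": ["g1", "g2"]},
    )


def random_partition_pair(n, seed):
    rng = np.random.default_rng(seed)
    k1 = int(rng.integers(1, max(2, n // 2)))
    k2 = int(rng.integers(1, max(2, n // 2)))
    pred = {i: int(rng.integers(0, k1)) for i in range(n)}
    true = {i: int(rng.integers(0, k2)) for i in range(n)}
    return pred, true


@pytest.fixture
def partition_pairs():
    return random_partition_pair
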