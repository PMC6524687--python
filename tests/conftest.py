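import networkx as nx
import numpy as np
import pytest

from pmen.io import OtuTable
from pmen.network import EcologicalNetwork
from pmen.similarity import SimilarityMatrix


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 OTUs x 4 samples, two groups, with taxonomy."""
    return OtuTable(
        otu_ids=["OTU1", "OTU2", "OTU3"],
        sample_ids=["A1", "A2", "B1", "B2"],
        values=np.array([[10, 20, 5, 1], [5, 5, 5, 5], [0, 3, 8, 2]], float),
        units="counts",
        taxonomy={"OTU1": ("Bacteria", "Firmicutes", "Clostridia"),
                  "OTU2": ("Bacteria", "Bacteroidetes")},
        group_of={"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
    )


def make_network(edges, st=0.5) -> EcologicalNetwork:
    """Network from (u, v[, weight[, sign]]) tuples; defaults weight 0.8, sign +1."""
    g = nx.Graph()
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else 0.8
        s = e[3] if len(e) > 3 else 1
        g.add_edge(u, v, weight=w, sign=s)
    return EcologicalNetwork(graph=g, st_used=st)


def planted_block_similarity(seed, n_blocks=5, block_size=30,
                             lo_range=(0.0, 0.4), hi_range=(0.75, 0.95)):
    """Similarity matrix with dense high blocks on a weak background."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    sim = rng.uniform(*lo_range, (n, n))
    for b in range(n_blocks):
        s = slice(block_size * b, block_size * (b + 1))
        sim[s, s] = rng.uniform(*hi_range, (block_size, block_size))
    sim = np.triu(sim, 1)
    sim = sim + sim.T
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(otu_ids=[f"O{i}" for i in range(n)], sim=sim,
                            sign=np.ones((n, n), dtype=int))


def bfs_distances(adj: dict, source):
    """Brute-force breadth-first shortest-path hop counts (test oracle)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist
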