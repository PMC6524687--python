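"""Signed co-occurrence network construction and global topology indices.

Edges join OTU pairs whose absolute Pearson correlation meets the RMT
threshold St; each edge carries the |r| as weight and the sign of r
(positive = co-occurrence, negative = co-exclusion).  All topological
indices are computed on the unweighted topology (distances in hops), the
convention of molecular ecological network analysis; weights are kept on
the edges for the signed OTU-degree sums used in the clinical-association
step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EcologicalNetwork",
    "ModulePartition",
    "NetworkIndices",
    "build_network",
    "detect_modules",
    "modularity_q",
    "global_indices",
    "power_law_r2",
    "module_composition",
]


@dataclass
class EcologicalNetwork:
    """Signed weighted undirected network over OTUs.

    Wraps a networkx Graph whose edges carry ``weight`` (|r| >= st) and
    ``sign`` (+1/-1) attributes.  Isolated OTUs are excluded.
    """

    graph: nx.Graph
    st_used: float

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise ValueError("self-loops are not allowed")
        if any(d == 0 for _, d in self.graph.degree()):
            raise ValueError("isolated nodes must be excluded")
        for _, _, data in self.graph.edges(data=True):
            if data["weight"] < self.st_used - 1e-12:
                raise ValueError("edge weight below the similarity threshold")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def negative_fraction(self) -> float:
        neg = sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] < 0)
        return neg / self.n_edges if self.n_edges else 0.0

    # -- exports -------------------------------------------------------
    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            dict(source=u, target=v, weight=d["weight"], sign=d["sign"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])

    def write_edge_list(self, path) -> None:
        self.to_edge_list().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity score."""

    membership: dict
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def module_nodes(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, []).append(node)
        return out


@dataclass
class NetworkIndices:
    """The standard panel of global network properties."""

    network_size: int
    total_links: int
    average_degree: float
    average_path_distance: float
    average_clustering: float
    harmonic_geodesic_distance: float
    power_law_r2: float | None
    modularity: float
    module_count: int
    negative_link_fraction: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Network size": self.network_size,
                "Total links": self.total_links,
                "Average degree": self.average_degree,
                "Average path distance": self.average_path_distance,
                "Average clustering coefficient": self.average_clustering,
                "Average harmonic geodesic distance": self.harmonic_geodesic_distance,
                "R2 of power-law": self.power_law_r2,
                "Modularity": self.modularity,
                "Module count": self.module_count,
                "Negative link fraction": self.negative_link_fraction,
            }
        )


def build_network(similarity, st: float) -> EcologicalNetwork:
    """Cut the signed network from a SimilarityMatrix at threshold `st`.

    Every pair with |r| >= st (boundary included — St is the *minimal*
    link strength) becomes an edge; OTUs left without any edge are
    dropped.
    """
    if not 0 < st <= 1:
        raise ValueError("st must lie in (0, 1]")
    sim, sign = similarity.sim, similarity.sign
    g = nx.Graph()
    n = similarity.order
    iu, ju = np.triu_indices(n, k=1)
    hit = sim[iu, ju] >= st
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(
            similarity.otu_ids[i], similarity.otu_ids[j],
            weight=float(sim[i, j]), sign=int(sign[i, j]),
        )
    if g.number_of_edges() == 0:
        raise ValueError(f"no similarity reaches the threshold {st}; empty network")
    return EcologicalNetwork(graph=g, st_used=st)


def modularity_q(graph: nx.Graph, membership: dict) -> float:
    """Direct Newman modularity: Q = sum_s [ l_s/E - (d_s/2E)^2 ].

    l_s = intra-module edge count, d_s = total degree of module s.  Kept
    as an explicit formula so the partition returned by the greedy search
    can be checked against it independently.
    """
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict = {}
    degree_sum: dict = {}
    for u, v in graph.edges():
        if membership[u] == membership[v]:
            intra[membership[u]] = intra.get(membership[u], 0) + 1
    for node, deg in graph.degree():
        s = membership[node]
        degree_sum[s] = degree_sum.get(s, 0) + deg
    q = 0.0
    for s in set(membership.values()):
        q += intra.get(s, 0) / m - (degree_sum.get(s, 0) / (2 * m)) ** 2
    return q


def detect_modules(net: EcologicalNetwork) -> ModulePartition:
    """Greedy agglomerative (CNM) modularity maximisation.

    Deterministic for a fixed graph: nodes are inserted in sorted order
    before the greedy merge, and module ids are renumbered by the sorted
    smallest member so repeated runs label modules identically.
    """
    # rebuild with lexicographic node order for reproducible tie-breaking
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes, key=str))
    g.add_edges_from(sorted((tuple(sorted(e, key=str)) for e in net.graph.edges),
                            key=lambda e: (str(e[0]), str(e[1]))))
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted((sorted(c, key=str) for c in communities),
                         key=lambda c: str(c[0]))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    return ModulePartition(membership=membership, q=modularity_q(g, membership))


def _path_distances(graph: nx.Graph) -> tuple[float, float]:
    """(average path distance over connected pairs, harmonic geodesic distance).

    Disconnected pairs are excluded from the arithmetic mean but contribute
    zero reciprocal distance to the harmonic mean — which is why both are
    reported for fragmented networks.
    """
    n = graph.number_of_nodes()
    total = 0.0
    reciprocal = 0.0
    connected_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for d in lengths.values():
            if d > 0:
                total += d
                reciprocal += 1.0 / d
                connected_pairs += 1
    avg_path = total / connected_pairs if connected_pairs else float("nan")
    harmonic = n * (n - 1) / reciprocal if reciprocal else float("nan")
    return avg_path, harmonic


def degree_frequency_r2(ks, freq) -> float:
    """R^2 of the OLS fit of log10(frequency) on log10(degree)."""
    fit = stats.linregress(np.log10(np.asarray(ks, float)),
                           np.log10(np.asarray(freq, float)))
    return float(fit.rvalue ** 2)


def power_law_r2(net: EcologicalNetwork | nx.Graph) -> float | None:
    """R^2 of the log-log OLS fit of degree frequency against degree.

    Scale-free topology shows as a straight line of log10 f(k) on
    log10 k.  Needs at least 3 distinct degree values; otherwise the fit
    is undefined and None is returned (logged, not raised).
    """
    graph = net.graph if isinstance(net, EcologicalNetwork) else net
    degrees = np.array([d for _, d in graph.degree()])
    ks, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if ks.size < 3:
        logger.warning("power-law fit undefined: only %d distinct degree value(s)",
                       ks.size)
        return None
    return degree_frequency_r2(ks, freq)


def global_indices(net: EcologicalNetwork,
                   partition: ModulePartition | None = None) -> NetworkIndices:
    """Compute the full panel of global indices on the unweighted topology."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if partition is None:
        partition = detect_modules(net)
    g = net.graph
    avg_path, harmonic = _path_distances(g)
    return NetworkIndices(
        network_size=net.n_nodes,
        total_links=net.n_edges,
        average_degree=2.0 * net.n_edges / net.n_nodes,
        average_path_distance=avg_path,
        average_clustering=nx.average_clustering(g),
        harmonic_geodesic_distance=harmonic,
        power_law_r2=power_law_r2(net),
        modularity=partition.q,
        module_count=partition.n_modules,
        negative_link_fraction=net.negative_fraction(),
    )


def module_composition(net: EcologicalNetwork, partition: ModulePartition,
                       taxonomy: dict | None = None,
                       min_size: int = 5) -> pd.DataFrame:
    """Per-module phylum composition and signed intra-module link counts.

    Only modules with at least `min_size` nodes are reported (small
    modules carry little co-occurrence signal).  OTUs without a taxonomy
    entry are tallied as ``unclassified``.
    """
    taxonomy = taxonomy or {}

    def phylum(otu) -> str:
        lineage = taxonomy.get(otu, ())
        return lineage[1] if len(lineage) >= 2 and lineage[1] else "unclassified"

    rows = []
    for mod, members in sorted(partition.module_nodes().items()):
        if len(members) < min_size:
            continue
        member_set = set(members)
        pos = neg = 0
        for u, v, d in net.graph.edges(members, data=True):
            if u in member_set and v in member_set:
                if d["sign"] < 0:
                    neg += 1
                else:
                    pos += 1
        comp: dict[str, int] = {}
        for otu in members:
            comp[phylum(otu)] = comp.get(phylum(otu), 0) + 1
        total = pos + neg
        rows.append(
            dict(module=mod, n_nodes=len(members),
                 composition=dict(sorted(comp.items())),
                 positive_links=pos, negative_links=neg,
                 negative_ratio=neg / total if total else float("nan"))
        )
    return pd.DataFrame(
        rows, columns=["module", "n_nodes", "composition", "positive_links",
                       "negative_links", "negative_ratio"],
    )
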