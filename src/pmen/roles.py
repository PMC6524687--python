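"""Within-module degree (Zi) and participation coefficient (Pi) node roles.

The Guimera-Amaral role taxonomy classifies nodes by two coordinates:
Zi, a z-score of a node's link count into its own module relative to its
module mates, and Pi = 1 - sum_s (k_is / k_i)^2, how evenly the node's
links spread over modules.  The ecological reading: peripherals are
specialists, module hubs and connectors are generalists (the putative
keystone taxa), and network hubs are super-generalists.

Category cut-offs: module hubs Zi > 2.5 and Pi <= 0.62; connectors
Pi > 0.62 and Zi <= 2.5; network hubs both high; peripherals both low.
Both boundaries belong to the "<=" side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "within_module_z",
    "participation",
    "classify",
    "zp_table",
    "keystone_nodes",
    "ZI_CUTOFF",
    "PI_CUTOFF",
]

ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62

PERIPHERAL = "peripheral"
CONNECTOR = "connector"
MODULE_HUB = "module hub"
NETWORK_HUB = "network hub"


def _intra_degree(graph, membership) -> dict:
    """kappa_i: number of links of node i to nodes of its own module."""
    kappa = {node: 0 for node in graph}
    for u, v in graph.edges():
        if membership[u] == membership[v]:
            kappa[u] += 1
            kappa[v] += 1
    return kappa


def within_module_z(net, partition) -> dict:
    """Zi per node: z-score of the intra-module link count within the module.

    Uses the population standard deviation over the module's members; when
    every member has the same intra-module degree (cliques, singletons)
    the z-score is defined as 0 so the statistic stays finite.
    """
    graph = net.graph
    membership = partition.membership
    kappa = _intra_degree(graph, membership)
    zi = {}
    for mod, members in partition.module_nodes().items():
        values = np.array([kappa[m] for m in members], dtype=float)
        mean, sd = values.mean(), values.std()  # population SD
        for m in members:
            zi[m] = float((kappa[m] - mean) / sd) if sd > 0 else 0.0
    return zi


def participation(net, partition) -> dict:
    """Pi per node: 1 - sum over modules of (links into module / degree)^2."""
    graph = net.graph
    membership = partition.membership
    pi = {}
    for node in graph:
        k_i = graph.degree(node)
        into: dict = {}
        for nbr in graph.neighbors(node):
            s = membership[nbr]
            into[s] = into.get(s, 0) + 1
        pi[node] = float(1.0 - sum((k_s / k_i) ** 2 for k_s in into.values()))
    return pi


def classify(zi: float, pi: float) -> str:
    """Four-way role from the (Zi, Pi) plane; boundaries inclusive on <=."""
    if zi > ZI_CUTOFF:
        return NETWORK_HUB if pi > PI_CUTOFF else MODULE_HUB
    return CONNECTOR if pi > PI_CUTOFF else PERIPHERAL


def zp_table(net, partition, taxonomy: dict | None = None) -> pd.DataFrame:
    """One row per node: module, Zi, Pi, role category and taxonomy labels."""
    taxonomy = taxonomy or {}
    zi = within_module_z(net, partition)
    pi = participation(net, partition)
    rows = []
    for node in sorted(net.graph.nodes, key=str):
        lineage = taxonomy.get(node, ())
        rows.append(
            dict(
                node=node,
                module=partition.membership[node],
                zi=zi[node],
                pi=pi[node],
                category=classify(zi[node], pi[node]),
                phylum=lineage[1] if len(lineage) >= 2 else "unclassified",
                genus=lineage[5] if len(lineage) >= 6 else "unclassified",
            )
        )
    return pd.DataFrame(rows, columns=["node", "module", "zi", "pi", "category",
                                       "phylum", "genus"])


def keystone_nodes(zp: pd.DataFrame) -> list:
    """Putative keystone taxa: module hubs, network hubs and connectors."""
    keep = zp["category"].isin([MODULE_HUB, NETWORK_HUB, CONNECTOR])
    return list(zp.loc[keep, "node"])
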