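"""Degree-preserving random-network ensembles and index significance tests.

Because each group yields a single empirical network, index differences
cannot be tested across biological replicates; instead each network is
compared against an ensemble of degree-preserving (Maslov-Sneppen double
edge swap) randomisations, and networks are compared to each other by a
two-sample Student t-test whose standard deviations come from the two
null ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import EcologicalNetwork, detect_modules, global_indices

logger = logging.getLogger(__name__)

__all__ = ["NullEnsemble", "rewire", "ensemble_indices", "compare_networks"]

#: the four topological indices summarised for random networks
NULL_INDICES = (
    "average_path_distance",
    "average_clustering",
    "harmonic_geodesic_distance",
    "modularity",
)


@dataclass
class NullEnsemble:
    """Per-index distributions over an ensemble of degree-preserving rewirings."""

    source: str
    values: pd.DataFrame  # one row per random network, one column per index

    @property
    def size(self) -> int:
        return len(self.values)

    def mean(self) -> pd.Series:
        return self.values.mean()

    def sd(self) -> pd.Series:
        return self.values.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean(), "sd": self.sd()})


def rewire(net: EcologicalNetwork, swaps_per_edge: int = 10,
           seed: int | None = None) -> EcologicalNetwork:
    """Randomise a network by double edge swaps, preserving every degree.

    Each attempt picks two edges (a,b), (c,d) and rewires them to (a,d),
    (c,b); swaps creating self-loops or duplicate edges are rejected.  The
    number of attempts is ``swaps_per_edge * E``.  Edge weight/sign
    attributes travel with the rewired stubs (weight from the (a,b) edge
    goes to (a,d), etc.), though null-model indices only use topology.
    Graphs with no valid swap (e.g. a triangle) come back unchanged.
    """
    rng = np.random.default_rng(seed)
    g = net.graph.copy()
    edges = [tuple(e) for e in g.edges()]
    m = len(edges)
    if m < 2:
        return EcologicalNetwork(graph=g, st_used=net.st_used)
    attempts = swaps_per_edge * m
    swapped = 0
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        attr_ab = dict(g.edges[a, b])
        attr_cd = dict(g.edges[c, d])
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, **attr_ab)
        g.add_edge(c, b, **attr_cd)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swapped += 1
    if swapped == 0:
        logger.info("no valid double edge swap found; returning a copy")
    return EcologicalNetwork(graph=g, st_used=net.st_used)


def ensemble_indices(net: EcologicalNetwork, n: int = 100,
                     swaps_per_edge: int = 10,
                     seed: int | None = None) -> NullEnsemble:
    """Index distributions over `n` seeded degree-preserving rewirings.

    Member seeds are derived from the master seed by a counter so the
    ensemble is reproducible and members are independent by construction.
    """
    if n < 2:
        raise ValueError("ensemble size must be >= 2")
    base = np.random.SeedSequence(seed)
    child_seeds = base.generate_state(n) % (2**31)
    rows = []
    for k in range(n):
        random_net = rewire(net, swaps_per_edge=swaps_per_edge,
                            seed=int(child_seeds[k]))
        partition = detect_modules(random_net)
        idx = global_indices(random_net, partition)
        rows.append({name: getattr(idx, name) for name in NULL_INDICES})
    return NullEnsemble(source=str(net.st_used), values=pd.DataFrame(rows))


def compare_networks(index_a: float, ens_a: NullEnsemble,
                     index_b: float, ens_b: NullEnsemble,
                     index_name: str) -> tuple[float, float]:
    """Student t-test between two networks' values of one index.

    t = (a - b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the standard deviations
    taken from the two null ensembles; two-sided p on Welch-Satterthwaite
    degrees of freedom (ensemble variances can differ by orders of
    magnitude, so pooled df would be anti-conservative).
    """
    s_a = float(ens_a.sd()[index_name])
    s_b = float(ens_b.sd()[index_name])
    n_a, n_b = ens_a.size, ens_b.size
    va, vb = s_a**2 / n_a, s_b**2 / n_b
    if va + vb == 0:
        # degenerate: both ensembles constant
        logger.warning("both null SDs are zero for %s; degenerate comparison",
                       index_name)
        if index_a == index_b:
            return 0.0, 1.0
        return float(np.sign(index_a - index_b) * np.inf), 0.0
    t = (index_a - index_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        (va**2 / (n_a - 1) if n_a > 1 else 0.0)
        + (vb**2 / (n_b - 1) if n_b > 1 else 0.0)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p
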