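"""Model/Results interface over the network pipeline.

`CooccurrenceNetwork` is the model: it holds one group's (or cohort's)
OTU table plus the preprocessing choices, and `fit()` runs the chain
prevalence filter -> relative abundance -> |Pearson| similarity -> RMT
threshold -> signed network -> modules -> topology indices -> Zi-Pi roles
-> null ensemble, returning a `NetworkFitResults` that carries every
intermediate product, a Table-style `summary()`, and comparison /
plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from . import roles as _roles
from .association import otu_degree
from .network import (EcologicalNetwork, ModulePartition, NetworkIndices,
                      build_network, detect_modules, global_indices,
                      module_composition)
from .nullmodel import NULL_INDICES, NullEnsemble, compare_networks, ensemble_indices
from .similarity import SimilarityMatrix, ThresholdScan, pearson_similarity, scan_threshold

__all__ = ["CooccurrenceNetwork", "NetworkFitResults"]


class CooccurrenceNetwork:
    """RMT-thresholded signed co-occurrence network model for an OTU table.

    Parameters
    ----------
    table : OtuTable
        Count table.  If `group` is given the table is restricted to that
        group's samples and the prevalence screen is applied within it.
    group : str, optional
        Group label to model (requires `table.group_of`).
    rarefy_depth : int, optional
        Rarefaction depth; None skips rarefaction (e.g. for pre-rarefied
        tables).
    prevalence : float
        Strict-majority detection fraction: keep an OTU iff it is present
        (> 0) in more than this fraction of the group's samples.
    rarefy_seed : int, optional
        Seed for the rarefaction subsampling.

    Examples
    --------
    >>> model = CooccurrenceNetwork(table, group="T0", rarefy_depth=None)
    >>> res = model.fit(seed=7)
    >>> res.st, res.indices.average_degree  # doctest: +SKIP
    """

    def __init__(self, table: _io.OtuTable, group: str | None = None,
                 rarefy_depth: int | None = None, prevalence: float = 0.5,
                 rarefy_seed: int | None = None):
        self.raw_table = table
        self.group = group
        self.prevalence = prevalence
        processed = table
        if rarefy_depth is not None:
            processed = _io.rarefy(processed, rarefy_depth, seed=rarefy_seed)
        if group is not None:
            processed = _io.prevalence_filter(processed, group, prevalence)
        elif prevalence is not None and group is None and table.group_of:
            # whole-cohort model: no group restriction, keep table as is
            pass
        self.table = processed
        self.rel_table = _io.relative_abundance(processed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_of: dict | None = None,
                       taxonomy: dict | None = None, **kwargs) -> "CooccurrenceNetwork":
        """Build from an OTU x sample count DataFrame."""
        table = _io.OtuTable(
            otu_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            units="counts",
            taxonomy=taxonomy or {},
            group_of=group_of or {},
        )
        return cls(table, **kwargs)

    def similarity(self) -> SimilarityMatrix:
        return pearson_similarity(self.rel_table)

    def fit(self, st: float | None = None, grid_start: float = 0.30,
            grid_step: float = 0.01, alpha: float = 0.05,
            n_random: int = 100, swaps_per_edge: int = 10,
            min_module_size: int = 5,
            seed: int | None = None) -> "NetworkFitResults":
        """Fit the network: choose St (unless imposed), build, and summarise.

        `st=None` runs the RMT threshold scan; a float (e.g. 0.660, the
        published common threshold) imposes the cut directly.  `n_random`
        degree-preserving rewirings form the null ensemble (0 skips it).
        """
        sim = self.similarity()
        scan = None
        if st is None:
            scan = scan_threshold(sim, grid_start=grid_start,
                                  grid_step=grid_step, alpha=alpha)
            st = scan.st
        net = build_network(sim, st)
        partition = detect_modules(net)
        indices = global_indices(net, partition)
        zp = _roles.zp_table(net, partition, self.table.taxonomy)
        null = None
        if n_random:
            null = ensemble_indices(net, n=n_random,
                                    swaps_per_edge=swaps_per_edge, seed=seed)
        composition = module_composition(net, partition, self.table.taxonomy,
                                         min_size=min_module_size)
        return NetworkFitResults(
            model=self, similarity=sim, scan=scan, st=float(st), network=net,
            partition=partition, indices=indices, zp=zp, null=null,
            composition=composition,
        )


@dataclass
class NetworkFitResults:
    """Everything a fitted co-occurrence network carries."""

    model: CooccurrenceNetwork
    similarity: SimilarityMatrix
    scan: ThresholdScan | None
    st: float
    network: EcologicalNetwork
    partition: ModulePartition
    indices: NetworkIndices
    zp: pd.DataFrame
    null: NullEnsemble | None
    composition: pd.DataFrame

    # -- derived -------------------------------------------------------
    def degrees(self, sign_filter: str = "all", mode: str = "strength") -> pd.Series:
        return pd.Series(otu_degree(self.network, sign_filter, mode)).sort_index()

    def keystones(self) -> list:
        return _roles.keystone_nodes(self.zp)

    def role_counts(self) -> pd.Series:
        return self.zp["category"].value_counts()

    def summary(self) -> str:
        """Table-style text panel: empirical indices plus null mean +/- SD."""
        label = self.model.group or "network"
        lines = [f"Co-occurrence network fit [{label}]  (St = {self.st:.3f})",
                 "-" * 56]
        emp = self.indices.as_series()
        for name, value in emp.items():
            if value is None:
                value_s = "undefined"
            elif isinstance(value, float):
                value_s = f"{value:.3f}"
            else:
                value_s = str(value)
            lines.append(f"{name:<38}{value_s:>16}")
        if self.null is not None:
            lines.append("-" * 56)
            lines.append(f"Random networks (n = {self.null.size}, degree-preserving)")
            mean, sd = self.null.mean(), self.null.sd()
            pretty = {
                "average_path_distance": "Average path distance",
                "average_clustering": "Average clustering coefficient",
                "harmonic_geodesic_distance": "Average harmonic geodesic distance",
                "modularity": "Modularity",
            }
            for key in NULL_INDICES:
                lines.append(
                    f"{pretty[key]:<38}{mean[key]:>9.3f} +/- {sd[key]:.3f}"
                )
        return "\n".join(lines)

    def compare(self, other: "NetworkFitResults", index_name: str) -> tuple[float, float]:
        """Student t-test of one index against another fitted network.

        Standard deviations come from the two null ensembles, which must
        have been computed (`n_random > 0`) on both sides.
        """
        if self.null is None or other.null is None:
            raise ValueError("both fits need a null ensemble for comparison")
        return compare_networks(
            getattr(self.indices, index_name), self.null,
            getattr(other.indices, index_name), other.null, index_name,
        )

    # -- plotting ------------------------------------------------------
    def plot_zp(self, ax=None):
        """Z-P scatter with the role-classification cut lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        colors = {"peripheral": "#999999", "connector": "#1f77b4",
                  "module hub": "#d62728", "network hub": "#9467bd"}
        for cat, sub in self.zp.groupby("category"):
            ax.scatter(sub["pi"], sub["zi"], s=18, label=cat,
                       color=colors.get(cat, "k"), alpha=0.8)
        ax.axhline(_roles.ZI_CUTOFF, ls="--", lw=0.8, color="k")
        ax.axvline(_roles.PI_CUTOFF, ls="--", lw=0.8, color="k")
        ax.set_xlabel("Among-module connectivity (Pi)")
        ax.set_ylabel("Within-module connectivity (Zi)")
        ax.legend(fontsize=7)
        return ax

    def plot_module_composition(self, ax=None):
        """Stacked bar of phylum composition for the reported modules."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        comp = self.composition
        if comp.empty:
            ax.set_title("no module of reportable size")
            return ax
        phyla = sorted({p for c in comp["composition"] for p in c})
        bottom = np.zeros(len(comp))
        for phylum in phyla:
            heights = np.array([c.get(phylum, 0) for c in comp["composition"]], float)
            ax.bar([str(m) for m in comp["module"]], heights, bottom=bottom,
                   label=phylum)
            bottom += heights
        ax.set_xlabel("module")
        ax.set_ylabel("nodes")
        ax.legend(fontsize=7)
        return ax
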