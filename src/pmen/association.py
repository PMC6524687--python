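"""Signed OTU degrees and Spearman association with clinical tumour markers.

The OTU degree of a node is the sum of the strengths (|r| weights) of its
links; splitting the sum by link sign gives positive and negative OTU
degrees, interpreted as the node's total co-occurrence and co-exclusion
strength.  Rank (Spearman) correlations relate these network quantities —
and the relative abundances of keystone OTUs — to serum tumour markers
(CA242, CEA, CA199, CA724).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "otu_degree",
    "spearman",
    "degree_marker_table",
    "keystone_marker_association",
]

MARKERS = ("CA242", "CEA", "CA199", "CA724")
DEGREE_VARIANTS = ("all", "negative", "positive")


@dataclass
class AssociationResult:
    variable: str
    marker: str
    rho: float | None
    p: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.rho is not None


def otu_degree(net, sign_filter: str = "all", mode: str = "strength") -> dict:
    """Per-node degree restricted by link sign.

    `mode="strength"` (default) sums the |r| edge weights — the OTU degree
    as the sum of link strengths; `mode="count"` counts the links instead.
    `sign_filter` is one of ``all``, ``positive``, ``negative``.
    """
    if sign_filter not in ("all", "positive", "negative"):
        raise ValueError(f"unknown sign filter {sign_filter!r}")
    if mode not in ("strength", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {node: 0.0 for node in net.graph}
    for u, v, d in net.graph.edges(data=True):
        if sign_filter == "positive" and d["sign"] < 0:
            continue
        if sign_filter == "negative" and d["sign"] >= 0:
            continue
        inc = d["weight"] if mode == "strength" else 1.0
        out[u] += inc
        out[v] += inc
    return out


def spearman(x, y) -> tuple[float | None, float | None, int]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Mid-ranks are used for ties; p comes from the t-approximation on
    n - 2 degrees of freedom.  Returns (None, None, n) when either vector
    is constant after removing incomplete pairs (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return None, None, n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def degree_marker_table(degree_summaries: pd.DataFrame,
                        marker_summaries: pd.DataFrame) -> pd.DataFrame:
    """Spearman grid of degree variants against tumour markers.

    Inputs are per-unit summaries (typically per-group means across
    treatment stages): `degree_summaries` has one row per unit and one
    column per degree variant ("all", "negative", "positive");
    `marker_summaries` has the same rows and one column per marker.  The
    result is a markers x variants grid of AssociationResult-style cells
    (rho, p, n), mirroring the conventional report layout.
    """
    common = degree_summaries.index.intersection(marker_summaries.index)
    if len(common) < 3:
        raise ValueError("need at least 3 units with complete data")
    rows = []
    for marker in marker_summaries.columns:
        row: dict = {"marker": marker}
        for variant in degree_summaries.columns:
            rho, p, n = spearman(degree_summaries.loc[common, variant],
                                 marker_summaries.loc[common, marker])
            row[f"{variant}_rho"] = rho
            row[f"{variant}_p"] = p
            row[f"{variant}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")


def keystone_marker_association(table, keystones: list, markers) -> pd.DataFrame:
    """Spearman of each keystone OTU's relative abundance vs each marker.

    Correlations run across the samples present in both the OTU table and
    the marker table, using pairwise-complete observations.
    """
    missing = [k for k in keystones if k not in table.otu_ids]
    if missing:
        raise KeyError(f"keystone OTU(s) absent from table: {missing}")
    shared = [s for s in table.sample_ids if s in markers.sample_ids]
    df = table.to_dataframe()[shared]
    rows = []
    for otu in keystones:
        abundance = df.loc[otu].to_numpy(dtype=float)
        for marker in markers.marker_names:
            mvals = markers.markers.loc[shared, marker].to_numpy(dtype=float)
            rho, p, n = spearman(abundance, mvals)
            rows.append(dict(otu=otu, marker=marker, rho=rho, p=p, n=n))
    return pd.DataFrame(rows, columns=["otu", "marker", "rho", "p", "n"])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional toggle; raw p is the default report)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
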