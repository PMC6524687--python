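"""OTU-table and sample-metadata input/output plus pre-network preprocessing.

The tabular dialect is the one most 16S pipelines emit: a tab-separated
matrix with OTU identifiers in the first column, one column per sample and
an optional trailing ``taxonomy`` column holding a semicolon-ranked lineage
(kingdom;phylum;...;genus).  Sample metadata is a second TSV keyed by
``sample_id`` with a ``group`` column and any number of continuous clinical
covariates (e.g. the tumour markers CA242, CEA, CA199, CA724).

Preprocessing follows the conventional molecular-ecological-network recipe:
rarefy counts to a common sequencing depth, keep only OTUs detected in a
strict majority of a group's replicate samples, then convert to relative
abundance before correlation analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: default rarefaction depth (sequences per sample)
DEFAULT_RAREFACTION_DEPTH = 39_796


class OtuTableError(ValueError):
    """Raised when an OTU table violates its structural contract."""


@dataclass
class OtuTable:
    """An OTU × sample abundance matrix with taxonomy and group design.

    Parameters
    ----------
    otu_ids : list of str
        Stable OTU identifiers (row labels). Must be unique.
    sample_ids : list of str
        Sample identifiers (column labels). Must be unique.
    values : ndarray of shape (n_otus, n_samples)
        Non-negative abundances; integer counts or proportions, as flagged
        by `units`.
    units : {"counts", "proportions"}
    taxonomy : dict, optional
        Map OTU id -> tuple of lineage ranks (kingdom ... genus strings).
    group_of : dict, optional
        Map sample id -> group label (e.g. ``H``, ``T0`` ... ``T5``).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    units: str = "counts"
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise OtuTableError("abundance values must be a 2-D matrix")
        n_otu, n_samp = self.values.shape
        if len(self.otu_ids) != n_otu or len(self.sample_ids) != n_samp:
            raise OtuTableError(
                f"label/matrix mismatch: {len(self.otu_ids)} OTU ids, "
                f"{len(self.sample_ids)} sample ids for a {self.values.shape} matrix"
            )
        if len(set(self.otu_ids)) != n_otu:
            raise OtuTableError("duplicate OTU ids")
        if len(set(self.sample_ids)) != n_samp:
            raise OtuTableError("duplicate sample ids")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise OtuTableError("abundances must be finite and non-negative")
        if self.units not in ("counts", "proportions"):
            raise OtuTableError(f"unknown units marker {self.units!r}")
        if self.units == "proportions":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise OtuTableError("proportion columns must sum to 1 +/- 1e-9")

    # -- convenience ---------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_of.get(s)
            if g is not None and g not in seen:
                seen.append(g)
        return seen

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)

    def phylum_of(self, otu_id: str) -> str:
        """Phylum-rank label for an OTU, ``"unclassified"`` when unknown."""
        lineage = self.taxonomy.get(otu_id, ())
        if len(lineage) >= 2 and lineage[1]:
            return lineage[1]
        return "unclassified"

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            group_of={s: self.group_of[s] for s in sample_ids if s in self.group_of},
        )

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return replace(
            self,
            otu_ids=list(otu_ids),
            values=self.values[idx, :],
            taxonomy={o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy},
        )


@dataclass
class MarkerTable:
    """Per-sample continuous clinical covariates (tumour markers).

    Missing values are stored as NaN; Spearman associations downstream use
    pairwise-complete observations.
    """

    sample_ids: list[str]
    markers: pd.DataFrame  # index = sample_ids, one column per marker

    def __post_init__(self) -> None:
        self.markers = self.markers.loc[self.sample_ids]

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    def values_for(self, marker: str) -> pd.Series:
        return self.markers[marker]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a ';'-ranked lineage string into rank labels, trimming blanks."""
    return tuple(part.strip() for part in str(text).split(";") if part.strip())


def read_otu_table(path, sep: str = "\t") -> OtuTable:
    """Read a TSV OTU table (rows = OTUs, columns = samples).

    The first row holds sample headers; an optional final ``taxonomy``
    column carries semicolon-ranked lineages.  Counts units are assumed.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise OtuTableError(f"duplicate OTU id(s): {dupes}")
    taxonomy: dict[str, tuple[str, ...]] = {}
    tax_cols = [c for c in df.columns if c.lower() == "taxonomy"]
    if tax_cols:
        tax_series = df[tax_cols[0]]
        taxonomy = {
            otu: parse_lineage(lin)
            for otu, lin in tax_series.items()
            if isinstance(lin, str) and lin.strip()
        }
        df = df.drop(columns=tax_cols)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise OtuTableError(
                f"non-numeric abundance in column {col!r}, row(s) {list(bad)[:5]}"
            ) from exc
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise OtuTableError(
            f"negative abundance at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return OtuTable(
        otu_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        units="counts",
        taxonomy=taxonomy,
    )


def write_otu_table(table: OtuTable, path, sep: str = "\t") -> None:
    """Re-emit a table in the same TSV dialect `read_otu_table` accepts."""
    df = table.to_dataframe()
    if table.units == "counts":
        df = df.astype(int)
    if table.taxonomy:
        df["taxonomy"] = [";".join(table.taxonomy.get(o, ())) for o in table.otu_ids]
    df.index.name = "otu_id"
    df.to_csv(path, sep=sep)


def read_metadata(path, table: OtuTable | None = None, sep: str = "\t") -> MarkerTable:
    """Read sample metadata (sample_id, group, marker columns).

    Side effect: when `table` is given, its ``group_of`` map is filled in
    from the ``group`` column, and every metadata sample id must exist in
    the table.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise OtuTableError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    if table is not None:
        unknown = set(df.index) - set(table.sample_ids)
        if unknown:
            raise OtuTableError(f"metadata samples absent from OTU table: {sorted(unknown)}")
        if "group" in df.columns:
            table.group_of.update(df["group"].astype(str).to_dict())
    marker_cols = [c for c in df.columns if c != "group"]
    markers = df[marker_cols].apply(pd.to_numeric, errors="coerce")
    return MarkerTable(sample_ids=list(df.index), markers=markers)


def write_metadata(table: OtuTable, markers: MarkerTable | None, path, sep: str = "\t") -> None:
    df = pd.DataFrame(index=pd.Index(table.sample_ids, name="sample_id"))
    df["group"] = [table.group_of.get(s, "") for s in table.sample_ids]
    if markers is not None:
        df = df.join(markers.markers)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None) -> OtuTable:
    """Subsample every sample column to `depth` sequences without replacement.

    Sampling is multivariate hypergeometric (each read drawn without
    replacement), so a column whose total equals `depth` is returned
    unchanged.  Samples with fewer than `depth` sequences are dropped with
    a warning rather than resampled with replacement.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.units != "counts":
        raise ValueError("rarefaction requires counts units")
    rng = np.random.default_rng(seed)
    counts = np.rint(table.values).astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: "
            f"{dropped[:10]}",
            stacklevel=2,
        )
    kept_samples = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.zeros((table.n_otus, len(kept_samples)), dtype=float)
    for j, col_idx in enumerate(np.flatnonzero(keep)):
        col = counts[:, col_idx]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return replace(
        table,
        sample_ids=kept_samples,
        values=out,
        group_of={s: table.group_of[s] for s in kept_samples if s in table.group_of},
    )


def prevalence_filter(table: OtuTable, group: str,
                      min_fraction: float = 0.5) -> OtuTable:
    """Restrict to one group and keep OTUs detected in a strict majority.

    An OTU is kept iff the number of the group's samples with abundance > 0
    strictly exceeds ``min_fraction * group_size`` (default: detected in
    more than 50% of replicate samples).  Ties at exactly the fraction are
    removed.
    """
    samples = [s for s in table.sample_ids if table.group_of.get(s) == group]
    if not samples:
        raise KeyError(f"unknown group label {group!r}")
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    sub = table.select_samples(samples)
    present = (sub.values > 0).sum(axis=1)
    keep = present > min_fraction * len(samples)
    kept_otus = [o for o, k in zip(sub.otu_ids, keep) if k]
    logger.info("prevalence filter: group %s kept %d/%d OTUs", group,
                len(kept_otus), table.n_otus)
    return sub.select_otus(kept_otus)


def relative_abundance(table: OtuTable) -> OtuTable:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    if table.units != "counts":
        raise ValueError("relative_abundance expects counts units")
    sums = table.values.sum(axis=0)
    if np.any(sums == 0):
        zero = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"all-zero sample column(s): {zero}")
    return replace(table, values=table.values / sums, units="proportions")
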