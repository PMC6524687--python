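"""Full-cohort orchestration: per-group network fits, cross-group tests,
marker associations, file outputs and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import degree_marker_table, otu_degree
from .datasets import percent_decrease, percent_increase
from .io import MarkerTable, OtuTable, write_otu_table
from .model import CooccurrenceNetwork, NetworkFitResults
from .nullmodel import NULL_INDICES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Configuration snapshot for a cohort run (all stages, one seed)."""

    groups: tuple[str, ...] | None = None  # None = every group in the table
    rarefy_depth: int | None = None
    prevalence: float = 0.5
    st: float | None = None  # impose a common threshold; None = detect per group
    grid_start: float = 0.30
    grid_step: float = 0.01
    alpha: float = 0.05
    n_random: int = 100
    swaps_per_edge: int = 10
    min_module_size: int = 5
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(table: OtuTable, markers: MarkerTable | None,
                 config: PipelineConfig, out_dir) -> dict:
    """Run every stage for every group and write all outputs under `out_dir`.

    Returns the run manifest (also written as ``manifest.json``): the
    config snapshot, the chosen St per group, and a checksummed inventory
    of every output file.  Outputs carry no timestamps, so re-running
    with the same inputs and config reproduces them byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = list(config.groups) if config.groups else table.groups
    if not groups:
        raise ValueError("no group labels available; provide metadata or groups")
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(groups)) % (2**31)

    fits: dict[str, NetworkFitResults] = {}
    st_of: dict[str, float] = {}
    for gi, group in enumerate(groups):
        logger.info("pipeline stage: group %s", group)
        try:
            model = CooccurrenceNetwork(
                table, group=group, rarefy_depth=config.rarefy_depth,
                prevalence=config.prevalence, rarefy_seed=int(seeds[2 * gi]),
            )
            res = model.fit(
                st=config.st, grid_start=config.grid_start,
                grid_step=config.grid_step, alpha=config.alpha,
                n_random=config.n_random, swaps_per_edge=config.swaps_per_edge,
                min_module_size=config.min_module_size,
                seed=int(seeds[2 * gi + 1]),
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at group {group!r}: {exc}") from exc
        fits[group] = res
        st_of[group] = res.st
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        write_otu_table(res.model.table, gdir / "filtered_table.tsv")
        if res.scan is not None:
            res.scan.to_tsv(gdir / "scan_trace.tsv")
        res.network.write_edge_list(gdir / "edge_list.tsv")
        res.network.write_graphml(gdir / "network.graphml")
        node_attr = res.zp.copy()
        node_attr["degree"] = node_attr["node"].map(
            otu_degree(res.network, "all", "count"))
        node_attr.to_csv(gdir / "node_attributes.tsv", sep="\t", index=False)
        res.composition.to_csv(gdir / "module_composition.csv", index=False)
        if res.null is not None:
            res.null.values.to_csv(gdir / "null_ensemble.tsv", sep="\t", index=False)

    # ---- cohort summary (empirical block + random mean +/- SD block)
    summary = pd.DataFrame({g: fits[g].indices.as_series() for g in groups})
    summary.loc["Identical threshold"] = [st_of[g] for g in groups]
    summary.to_csv(out / "summary.tsv", sep="\t")
    null_rows = []
    for key in NULL_INDICES:
        row = {}
        for g in groups:
            null = fits[g].null
            if null is not None:
                row[g] = f"{null.mean()[key]:.3f} +/- {null.sd()[key]:.3f}"
        null_rows.append(pd.Series(row, name=key))
    pd.DataFrame(null_rows).to_csv(out / "null_summary.tsv", sep="\t")

    # ---- cross-group comparisons
    if len(groups) >= 2 and config.n_random:
        comp_rows = []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                for key in NULL_INDICES:
                    t, p = fits[a].compare(fits[b], key)
                    comp_rows.append(dict(group_a=a, group_b=b, index=key, t=t, p=p))
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    else:
        logger.info("single group or no null ensemble: comparison stage skipped")

    # ---- associations with clinical markers
    if markers is not None and len(groups) >= 3:
        deg_rows = {}
        for g in groups:
            deg_rows[g] = {
                variant: float(np.mean(list(
                    otu_degree(fits[g].network, variant, "strength").values())))
                for variant in ("all", "negative", "positive")
            }
        degree_summaries = pd.DataFrame(deg_rows).T
        group_markers = pd.DataFrame({
            m: {
                g: float(np.nanmean([
                    markers.markers.loc[s, m] for s in table.sample_ids
                    if table.group_of.get(s) == g and s in markers.markers.index
                ] or [np.nan]))
                for g in groups
            }
            for m in markers.marker_names
        })
        try:
            assoc = degree_marker_table(degree_summaries, group_markers)
            assoc.to_csv(out / "degree_marker_associations.csv")
        except ValueError as exc:
            logger.warning("degree-marker association skipped: %s", exc)

    manifest = dict(
        version=__version__,
        config=asdict(config),
        groups=groups,
        st=st_of,
        files={},
    )
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(summary: pd.DataFrame, pairs: list[tuple[str, str]] | None = None) -> str:
    """Human-readable cohort report with percentage-change statements.

    For each (reference, other) group pair the change in average degree
    and in modularity is printed under *both* directional conventions —
    relative to the reference and relative to the other group — with the
    formula spelled out, because the two conventions differ and published
    summaries mix them.
    """
    def _row(name, alias):
        return summary.loc[name] if name in summary.index else summary.loc[alias]

    groups = list(summary.columns)
    if pairs is None:
        pairs = [(groups[0], g) for g in groups[1:]]
    lines = ["Cohort network report", "=" * 52,
             summary.to_string(float_format=lambda v: f"{v:.3f}"), ""]
    degree_row = _row("Average degree", "average_degree")
    modularity_row = _row("Modularity", "modularity")
    for ref, other in pairs:
        k_ref = float(degree_row[ref])
        k_oth = float(degree_row[other])
        m_ref = float(modularity_row[ref])
        m_oth = float(modularity_row[other])
        lines.append(f"{other} vs {ref}:")
        lines.append(
            f"  average degree: {percent_increase(k_ref, k_oth):+.1f}% of {ref} "
            f"[(k_{other}-k_{ref})/k_{ref}]; "
            f"{percent_decrease(k_oth, k_ref):+.1f}% decrease from {other} "
            f"[(k_{other}-k_{ref})/k_{other}]"
        )
        lines.append(
            f"  modularity: {percent_increase(m_ref, m_oth):+.1f}% of {ref} "
            f"[(m_{other}-m_{ref})/m_{ref}]; "
            f"{percent_decrease(m_oth, m_ref):+.1f}% decrease from {other} "
            f"[(m_{other}-m_{ref})/m_{other}]"
        )
    return "\n".join(lines)
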