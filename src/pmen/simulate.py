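"""Synthetic group-structured OTU tables with planted network structure.

The generator emulates the shape of a 16S chemotherapy-cohort dataset —
several groups of ~21 replicate faecal samples, several hundred OTUs —
while planting exactly the structures the pipeline is supposed to
recover: modular signed correlation blocks, designated cross-module
connector OTUs, and tumour-marker variables linearly coupled to network
quantities.

Latent model (per sample): each module m has a latent factor
f_m = sqrt(a) g + sqrt(1-a) h_m with a = rho_b / rho_w, so any two OTUs
of the same module correlate at rho_w and OTUs of different modules at
rho_b, with positive definiteness guaranteed by construction.  A chosen
subset of coordinates is reflected (z -> -z), turning the corresponding
within-module couplings negative: with a flipped fraction q the fraction
of negative within-module couplings is 2 q (1 - q), so the achievable
planted negative fraction is at most 1/2.

Connector OTUs load evenly on several module factors, and a few *anchor*
members of each spanned module split their loading between their module
factor and the connector's factor mix, which is what gives the connector
above-threshold links into every spanned module (loading purely on the
factor mix caps the connector-member correlation near sqrt(rho_w / span),
below any sensible threshold).

Latent values map to counts via b_i * exp(sigma * z) Poisson rates (a
lognormal-Poisson mixture), which preserves the planted Pearson sign
structure far better at moderate sigma than compositional simulators
would.  sigma trades two error sources against each other: the exp map
attenuates negative correlations more strongly than positive ones
(favouring small sigma), while Poisson counting noise on low-abundance
OTUs attenuates everything relative to sigma (favouring large sigma);
the default 0.35, with a moderate spread of baseline abundances, keeps
both distortions near 10%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerTable, OtuTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_table", "generate_markers"]

DEFAULT_GROUPS = ("H", "T0", "T1", "T2", "T3", "T4", "T5")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the package targets: 7 groups
    (healthy plus six chemotherapy stages) of 21 samples, 800 OTUs of
    which the planted modules cover a fraction, ~40k reads per sample so
    the default rarefaction depth is exercised.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    samples_per_group: int = 21
    n_otus: int = 800
    module_sizes: tuple[int, ...] = (30, 30, 25, 25, 20, 20)
    rho_within: float = 0.8
    rho_between: float = 0.1
    f_neg: float = 0.5
    n_connectors: int = 0
    connector_span: int = 4  # modules each connector loads on
    connector_strength: float = 1.0
    anchors_per_module: int = 5  # members per spanned module co-loading on the connector
    base_meanlog: float = 0.0
    base_sdlog: float = 0.8
    sigma: float = 0.35  # latent-to-abundance log scale
    zero_inflation: float = 0.0
    target_depth: int = 46_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_between < self.rho_within <= 1:
            raise ValueError("need 0 <= rho_between < rho_within <= 1")
        if not 0 <= self.f_neg <= 0.5:
            raise ValueError(
                "planted negative coupling fraction is limited to [0, 0.5] "
                "(axis reflection can make at most half of the within-module "
                "pairs negative)"
            )
        if sum(self.module_sizes) + self.n_connectors > self.n_otus:
            raise ValueError("module sizes plus connectors exceed the OTU count")
        if self.n_connectors and self.connector_span > len(self.module_sizes):
            raise ValueError("connector_span exceeds the module count")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: module membership, coupling signs, connectors."""

    module_of: dict[str, int | None]  # None = background noise OTU
    sign_of: dict[str, int]  # +-1 reflection applied to the latent axis
    connectors: list[str]
    connector_modules: dict[str, tuple[int, ...]]
    anchors: dict[str, list[str]] = field(default_factory=dict)
    marker_coupling: dict[str, float] = field(default_factory=dict)

    def membership_labels(self, otu_ids: list[str]) -> list[int]:
        """Integer labels for clustering comparison; background/connectors -1."""
        return [self.module_of.get(o) if self.module_of.get(o) is not None else -1
                for o in otu_ids]

    def latent_correlation(self, otu_ids: list[str], spec: SyntheticSpec) -> np.ndarray:
        """Signed latent correlation matrix implied by the factor model."""
        n = len(otu_ids)
        a = spec.rho_between / spec.rho_within if spec.rho_within > 0 else 0.0
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                oi, oj = otu_ids[i], otu_ids[j]
                mi, mj = self.module_of.get(oi), self.module_of.get(oj)
                if mi is None or mj is None or oi in self.connectors or oj in self.connectors:
                    continue  # background/connector couplings are structural, not rho_w/rho_b
                s = self.sign_of[oi] * self.sign_of[oj]
                rho = spec.rho_within if mi == mj else spec.rho_between
                corr[i, j] = corr[j, i] = s * rho
        return corr

    def to_json(self, path) -> None:
        payload = dict(
            module_of=self.module_of,
            sign_of=self.sign_of,
            connectors=self.connectors,
            connector_modules={k: list(v) for k, v in self.connector_modules.items()},
            anchors=self.anchors,
            marker_coupling=self.marker_coupling,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _flip_count(size: int, f_neg: float) -> int:
    """Coordinates to reflect so ~f_neg of within-module pairs turn negative.

    With q = flipped fraction, the negative pair fraction is 2q(1-q);
    invert for the smaller root.
    """
    if f_neg == 0:
        return 0
    q = (1.0 - math.sqrt(max(0.0, 1.0 - 2.0 * f_neg))) / 2.0
    return int(round(q * size))


def generate_table(spec: SyntheticSpec) -> tuple[OtuTable, GroundTruth]:
    """Generate the cohort OTU table and its ground truth.

    Deterministic for a fixed spec (the master seed is a spec field).
    All groups share the same planted correlation structure; they differ
    only by sampling noise, which is what the pipeline's per-group runs
    are meant to see through.
    """
    rng = np.random.default_rng(spec.seed)
    n_mod = len(spec.module_sizes)
    otu_ids = [f"OTU{i + 1}" for i in range(spec.n_otus)]

    # --- assign OTUs: modules first, then connectors, rest background
    module_of: dict[str, int | None] = {}
    sign_of: dict[str, int] = {}
    cursor = 0
    for m, size in enumerate(spec.module_sizes):
        members = otu_ids[cursor:cursor + size]
        cursor += size
        n_flip = _flip_count(size, spec.f_neg)
        flipped = set(rng.choice(size, size=n_flip, replace=False)) if n_flip else set()
        for k, otu in enumerate(members):
            module_of[otu] = m
            sign_of[otu] = -1 if k in flipped else 1
    connectors = otu_ids[cursor:cursor + spec.n_connectors]
    cursor += spec.n_connectors
    connector_modules: dict[str, tuple[int, ...]] = {}
    for c_idx, otu in enumerate(connectors):
        start = (c_idx * spec.connector_span) % n_mod
        span = tuple((start + k) % n_mod for k in range(spec.connector_span))
        connector_modules[otu] = span
        module_of[otu] = None
        sign_of[otu] = 1
    for otu in otu_ids[cursor:]:
        module_of[otu] = None
        sign_of[otu] = 1

    # --- anchors: unflipped module members co-loading on a connector's mix
    anchors_of: dict[str, list[str]] = {}
    anchor_connector: dict[str, str] = {}
    members_by_module = {m: [o for o in otu_ids if module_of[o] == m]
                         for m in range(n_mod)}
    for otu in connectors:
        anchors_of[otu] = []
        for m in connector_modules[otu]:
            candidates = [o for o in members_by_module[m]
                          if sign_of[o] == 1 and o not in anchor_connector]
            take = min(spec.anchors_per_module, len(candidates))
            chosen = [str(o) for o in rng.choice(candidates, size=take, replace=False)]
            for o in chosen:
                anchor_connector[o] = otu
            anchors_of[otu].extend(chosen)

    # --- latent draws
    a = spec.rho_between / spec.rho_within if spec.rho_within > 0 else 0.0
    n_samples_total = len(spec.groups) * spec.samples_per_group
    g_shared = rng.standard_normal(n_samples_total)
    h = rng.standard_normal((n_mod, n_samples_total))
    factors = math.sqrt(a) * g_shared + math.sqrt(1.0 - a) * h  # (n_mod, samples)

    # connector factor u_c: a *balanced contrast* of the spanned module
    # factors (+,+,-,-,...).  A plain average of module factors is nearly
    # proportional to the sample's total abundance, so the closure step
    # (relative abundance) subtracts most of its signal and destroys the
    # connector's planted correlations; a zero-sum contrast is orthogonal
    # to the total and passes through closure intact.  Anchors in a module
    # with a negative contrast coefficient simply use the reflected axis
    # (their links are negative, which the |r| network keeps as edges).
    # a private channel is mixed in on top of the contrast so the
    # connector's correlation with *regular* (non-anchor) span-module
    # members stays well below the sampling-noise floor — otherwise a
    # lucky factor realisation floods the connector with one module's
    # members and unbalances its participation
    contrast_share = 0.65
    u_of: dict[str, np.ndarray] = {}
    w_of: dict[str, float] = {}  # |corr(f_m, u_c)| for m in span
    contrast_of: dict[str, dict[int, int]] = {}
    for otu in connectors:
        span = connector_modules[otu]
        k = len(span)
        coeffs = {m: (1 if j % 2 == 0 else -1) for j, m in enumerate(span)}
        contrast_of[otu] = coeffs
        contrast = sum(coeffs[m] * factors[m] for m in span)
        u_of[otu] = (math.sqrt(contrast_share) * contrast / math.sqrt(k * (1.0 - a))
                     + math.sqrt(1.0 - contrast_share)
                     * rng.standard_normal(n_samples_total))
        w_of[otu] = math.sqrt(contrast_share * (1.0 - a) / k)

    # anchor loading split between own-module factor and the connector factor.
    # At rho_w = 0.85 this puts the anchor-mate latent |correlation| near 0.80
    # and anchor-connector near 0.84, both above any detected St
    p_anchor, q_anchor = 0.61, 0.58

    z = np.empty((spec.n_otus, n_samples_total))
    sqrt_rw = math.sqrt(spec.rho_within)
    resid = math.sqrt(1.0 - spec.rho_within)
    for i, otu in enumerate(otu_ids):
        m = module_of[otu]
        if otu in connector_modules:
            v = spec.connector_strength
            z[i] = (math.sqrt(v) * u_of[otu]
                    + math.sqrt(1.0 - v) * rng.standard_normal(n_samples_total))
        elif otu in anchor_connector:
            conn = anchor_connector[otu]
            w = w_of[conn]
            c_m = contrast_of[conn][m]
            sign_of[otu] = c_m  # anchors in "-" contrast modules ride the reflected axis
            var_pq = p_anchor**2 + q_anchor**2 + 2 * p_anchor * q_anchor * w
            z[i] = (p_anchor * c_m * factors[m] + q_anchor * u_of[conn]
                    + math.sqrt(1.0 - var_pq) * rng.standard_normal(n_samples_total))
        elif m is None:
            z[i] = rng.standard_normal(n_samples_total)
        else:
            z[i] = sign_of[otu] * (sqrt_rw * factors[m]
                                   + resid * rng.standard_normal(n_samples_total))

    # --- map to counts (lognormal-Poisson)
    base = rng.lognormal(spec.base_meanlog, spec.base_sdlog, size=spec.n_otus)
    expected_total = float(np.sum(base) * math.exp(spec.sigma**2 / 2.0))
    # 15% head-room above the requested depth so rarefaction rarely drops samples
    scale = 1.15 * spec.target_depth / expected_total
    rates = scale * base[:, None] * np.exp(spec.sigma * z)
    counts = rng.poisson(rates).astype(float)
    if spec.zero_inflation > 0:
        counts[rng.random(counts.shape) < spec.zero_inflation] = 0.0

    sample_ids = [f"{grp}.{k + 1}" for grp in spec.groups
                  for k in range(spec.samples_per_group)]
    group_of = {s: s.split(".")[0] for s in sample_ids}
    taxonomy = _synthetic_taxonomy(otu_ids, module_of, rng)
    table = OtuTable(otu_ids=otu_ids, sample_ids=sample_ids, values=counts,
                     units="counts", taxonomy=taxonomy, group_of=group_of)
    truth = GroundTruth(module_of=module_of, sign_of=sign_of,
                        connectors=list(connectors),
                        connector_modules=connector_modules,
                        anchors=anchors_of)
    return table, truth


_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Fusobacteria", "Verrucomicrobia")


def _synthetic_taxonomy(otu_ids, module_of, rng) -> dict[str, tuple[str, ...]]:
    """Synthetic lineages: each module leans towards one phylum, background mixed."""
    taxonomy = {}
    for otu in otu_ids:
        m = module_of[otu]
        if m is not None and rng.random() < 0.7:
            phylum = _PHYLA[m % len(_PHYLA)]
        else:
            phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
        taxonomy[otu] = ("Bacteria", phylum)
    return taxonomy


def generate_markers(quantity: pd.Series, coupling: dict[str, float],
                     noise_sd: float = 0.0,
                     seed: int | None = None) -> MarkerTable:
    """Tumour-marker values linearly coupled to a network quantity.

    ``marker = coupling[marker] * quantity + N(0, noise_sd)`` per unit
    (sample or group, whatever indexes `quantity`).  A negative coupling
    plants a negative monotone — hence Spearman-detectable — association.
    """
    rng = np.random.default_rng(seed)
    q = quantity.to_numpy(dtype=float)
    data = {}
    for marker, coef in coupling.items():
        data[marker] = coef * q + rng.normal(0.0, noise_sd, size=q.size)
    df = pd.DataFrame(data, index=quantity.index)
    return MarkerTable(sample_ids=list(quantity.index), markers=df)
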