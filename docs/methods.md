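# Methods

This note documents the models, numerical choices and limitations behind
`pmen`. It is the maintainer's account of *why* the code does what it
does; the README shows *how* to run it.

## Scope and model

A pMEN is an undirected, signed, weighted graph over OTUs. The underlying
statistical object is the matrix of Pearson correlations between OTU
relative-abundance profiles across a group's replicate samples; the
network keeps only entries whose absolute value reaches the
random-matrix-theory threshold St. Everything downstream — topology
indices, Zi–Pi roles, null ensembles, marker associations — is a function
of that graph. The approach assumes replicate samples within a group are
exchangeable draws from one community, that linear (Pearson) association
on relative abundances captures co-occurrence, and that a single St can
summarise the noise/signal transition for a whole matrix.

## Preprocessing

* **Rarefaction** subsamples each sample's counts to a common depth
  without replacement (multivariate hypergeometric), default 39,796
  sequences — the conventional depth for this assay scale. Samples below
  the depth are dropped, not resampled with replacement, which keeps the
  counts exactly hypergeometric. Rarefaction runs *before* the prevalence
  screen; detection (abundance > 0) is evaluated on the rarefied table.
  The order is exposed to callers who disagree (both operations are
  public and composable).
* **Prevalence filter**: an OTU is kept iff present in strictly more than
  `min_fraction` (default 0.5) of the group's samples. Ties at exactly
  half are removed; with 22 replicates an OTU present in 11 is out, in 12
  is in.
* **Relative abundance** divides each sample column by its sum.
  Correlations are computed on these proportions without a log transform
  — the simplest faithful reading of the source pipeline. Compositional
  closure is therefore part of the measured signal, deliberately: the
  synthetic-data results below quantify what closure does to planted
  structure.

## RMT threshold detection

For each candidate threshold `s` (grid 0.30–0.99, step 0.01) the
similarity matrix is pruned (entries < s zeroed, rows/columns with no
surviving off-diagonal entry removed, weighted matrix kept — not
binarised) and its eigenvalue spectrum is tested:

1. **Unfolding.** Near-degenerate eigenvalues (gap < 1e-10) are collapsed.
   Eigenvalues detached above the bulk — the Perron/module eigenvalues of
   a thresholded correlation matrix, operationally those above the bulk's
   75th percentile by more than five times the 10–90 percentile span —
   are excluded: they are non-universal (they encode the module count,
   not level statistics) and a smooth unfolding cannot track the density
   gap around them. The remaining spectrum is mapped through a monotone
   cubic (PCHIP) spline fit to ⌈N/20⌉+2 quantile knots of the empirical
   cumulative spectral function, which fixes the mean nearest-neighbour
   spacing at 1. Fewer than 30 usable eigenvalues stops the scan.
2. **Spacing test.** Spacings are binned (width 0.1 on [0, 3] plus an
   open tail). Expected masses come from the Poisson law `exp(−d)` or the
   GOE Wigner surmise. Adjacent bins are pooled until each expected count
   reaches 5 (Cochran's rule) and the chi-square statistic uses
   `df = pooled bins − 1` (no parameter is estimated from the data).
   Without pooling the test is anti-conservative: on true iid exponential
   spacings (n = 500) the unpooled version passed `p > 0.05` only 89% of
   the time; pooled, 95%.
3. **Acceptance.** St is the smallest grid value whose Poisson p-value
   exceeds α (default 0.05) *and stays above α for the next two grid
   points*. The stability rule guards against single-point acceptances:
   very sparse random matrices also show Poisson-like spacings, so an
   isolated acceptance deep in the noise regime is not trusted.

The scan is fully deterministic given the similarity matrix. On planted
block matrices (five 30-OTU blocks with |r| ~ U(0.75, 0.95) over a
U(0, 0.4) background) the chosen St lands inside the (0.40, 0.75) gap in
19 of 20 seeds.

## Topology, modules, roles

All distance/clustering/modularity indices use the **unweighted**
topology (hops), the molecular-ecological-network convention; weights
only enter the signed OTU-degree sums. Disconnected pairs are excluded
from the average path distance but contribute zero reciprocal to the
harmonic geodesic distance — the reason both are reported for fragmented
networks. The power-law `R²` is the squared correlation of an OLS fit of
log10(degree frequency) on log10(degree) over degrees with frequency ≥ 1;
fewer than three distinct degrees yields an undefined marker, not an
exception.

Module detection is greedy agglomerative (CNM) modularity maximisation on
the unweighted graph, with nodes and edges inserted in lexicographic
order so repeated runs are identical; the returned Q is re-evaluated with
the direct formula `Σ_s [l_s/E − (d_s/2E)²]` as an internal consistency
check. Zi uses the population standard deviation of intra-module link
counts, with `Zi = 0` for zero-variance (clique or singleton) modules so
the statistic stays finite. Role cut-offs: `Zi = 2.5` and `Pi = 0.62`,
both boundaries belonging to the "≤" side. Keystones = module hubs ∪
network hubs ∪ connectors.

## Null model and comparisons

The null is Maslov–Sneppen double edge swap: `10 × E` attempts, each
picking two edges (a,b), (c,d) and rewiring to (a,d), (c,b) unless a
self-loop or duplicate would result. This preserves every node's degree
exactly, which is the property the published random-network panel holds
fixed. Member seeds derive from the master seed through a
`SeedSequence` counter, so ensembles are reproducible and
order-insensitive. Ensemble summaries use the sample SD (n − 1). The
two-network comparison is `t = (a − b)/√(s_a²/n_a + s_b²/n_b)` with
Welch–Satterthwaite degrees of freedom — pooled df would be
anti-conservative when the two null variances differ by orders of
magnitude, which they routinely do (a sparse H-like network's null is far
more variable than a dense T-like one's).

## Clinical association

The OTU degree is the sum of link strengths (|r|) at a node; the positive
and negative variants restrict the sum by link sign, so positive +
negative = total exactly. Spearman correlations use mid-ranks and the
t-approximation on n − 2 df, with pairwise-complete observations. The
degree-versus-marker grid takes explicit per-unit summaries (default:
per-group means) because the sampling unit behind such tables is a
reporting choice; the caller owns it. Raw p-values are reported by
default (matching field practice); a Benjamini–Hochberg helper is
provided but off by default.

## Synthetic data generator

The generator emulates a chemotherapy-cohort 16S dataset: groups of ~21
replicate samples, several hundred OTUs, ~46k reads/sample so the default
rarefaction depth is exercised.

**Latent model.** Each module m has a factor
`f_m = √a·g + √(1−a)·h_m` with `a = ρ_b/ρ_w`; a member loads `√ρ_w` on
its factor, giving exactly ρ_w within and ρ_b between modules, positive
definite by construction. Reflecting a fraction q of member axes makes
`2q(1−q)` of within-module couplings negative, so the plantable
co-exclusion fraction caps at 1/2 (the generator validates this).

**Counts.** Abundances are lognormal-Poisson:
`counts ~ Poisson(b_i · exp(σ z))` with per-OTU baselines
`b_i ~ LogNormal(0, base_sdlog)` scaled to the target depth plus 15%
head-room. σ trades two error sources: the exp map attenuates negative
correlations more than positive ones (favouring small σ), while Poisson
counting noise on low-abundance OTUs attenuates everything relative to σ
(favouring large σ). Cohort defaults σ = 0.35, base_sdlog = 0.8 keep both
distortions near 10%; the strong-signal recovery fixtures use σ = 0.25,
base_sdlog = 0.5 where the planted correlations pass nearly unattenuated.

**Connectors.** A planted connector OTU loads on a factor `u_c` built as
a *balanced contrast* (+,+,−,−) of four module factors (65%) plus a
private channel (35%); designated anchor members of each spanned module
co-load on `u_c` (loadings p = 0.61 on the own-module factor, q = 0.58 on
`u_c`). Three findings from calibrating this design are worth recording:

* A plain factor *average* is nearly proportional to the sample total, so
  the relative-abundance step subtracts most of its signal (measured:
  anchor–connector correlation fell from 0.78 in counts to 0.63 in
  proportions while ordinary module pairs barely moved). The zero-sum
  contrast is orthogonal to the total and passes through closure intact.
* A Gram/PSD bound makes a connector's neighbourhood irreducibly dense:
  K neighbours each correlated r with one variable must be mutually
  correlated at ≈ r² for large K. That cross-module "web" itself delays
  the Poisson transition and inflates St toward the connector's own link
  strength — a structural tension in the method, not an implementation
  artefact.
* With 40 samples the empirical-correlation noise (sd ≈ 0.16) moves whole
  per-module anchor groups above or below St together.

Consequently per-seed connector classification is stochastic: at the
frozen strong-signal design it succeeds in ~70–80% of seeds (8/10 at the
canonical seed set), while module recovery (ARI ≥ 0.9), threshold
placement and the planted negative-link fraction (±0.1) succeed in 10/10.
The recovery tests assert exactly these calibrated rates.

**Markers.** `marker = coupling × quantity + N(0, noise_sd)` per unit; a
negative coupling plants a Spearman-detectable negative association, and
noise-free coupling gives ρ = −1 exactly.

**What passing these tests does and does not show.** The generator's
lognormal-Poisson counts preserve planted Pearson structure by design;
real 16S data have heavier-tailed abundance fluctuations, stronger
compositional coupling, zero inflation from detection limits and
phylogenetically structured noise, all of which attenuate correlations —
especially negative ones — more than the simulation does. Passing the
recovery suite shows the pipeline's inference machinery is correct, not
that real cohorts of 21 samples yield networks with these error rates.

## Reported percentage conventions

The bundled published index table supports two directional conventions
for percentage change, and published summaries mix them: degree changes
are quoted relative to the CRC-stage value ((k_T − k_H)/k_T; e.g. 56.4%
for T0 vs H) while modularity changes are quoted relative to the
reference group ((m_T5 − m_T0)/m_T0 = 16.1%; (m_H − m_T)/m_H = 44.5% for
T0). `pmen.pipeline.report` therefore prints both conventions with the
formula spelled out. One published cell (the T5-vs-H degree excess,
printed 58.6%) reproduces under no convention — recomputation gives
53.3% — and is treated as a typo; tests assert the cells that verify.

## Problem sizes

The test suite and the acceptance script run on deliberately compact
instances — 150–160-OTU matrices for threshold scans, 40-sample groups,
10–100-member null ensembles, ensembles of 10 for repeated-seed sweeps —
chosen so the full recovery suite measures the same transitions the
method exhibits at cohort scale while remaining quick to iterate on. The
pipeline itself has no such limits; a 7-group, 800-OTU cohort runs in
minutes on one core.

## Known limitations

* Pearson-on-proportions carries compositional artefacts; no
  centred-log-ratio or SparCC-style alternative is provided (out of
  scope).
* The greedy CNM module algorithm has a known resolution limit; module
  *counts* are therefore not treated as reproducible quantities across
  implementations.
* The RMT scan's "smallest accepted s" rule can accept below the signal
  gap on matrices whose noise block is already sparse; the two-point
  stability rule reduces but does not eliminate this.
* At 21–40 replicates the correlation noise floor (≈ n^{−1/2}) is the
  binding constraint on everything downstream; the generator's recovery
  rates quantify it.
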