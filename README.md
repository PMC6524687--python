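# pmen — RMT-thresholded molecular ecological networks for microbiome data

`pmen` infers **phylogenetic molecular ecological networks** (pMENs) from
16S OTU abundance tables: signed microbial co-occurrence networks whose
link-strength cutoff is chosen objectively by random matrix theory rather
than by an arbitrary correlation threshold. It is aimed at microbiome
researchers who want to compare intestinal (or other host-associated)
community interaction structure across cohorts or treatment stages — for
example healthy controls (H) versus colorectal-cancer patients across
chemotherapy stages (T0–T5) — and to relate network quantities to clinical
covariates such as the serum tumour markers CEA, CA199, CA242 and CA724.

## The method

Starting from a count table (OTUs × samples):

1. **Preprocessing** — rarefy every sample to a common depth (without
   replacement), keep only OTUs detected in a strict majority (> 50%) of a
   group's replicate samples, convert to relative abundance.
2. **Similarity** — the matrix `S_ij = |r_ij|` of absolute Pearson
   correlations between OTU abundance profiles, with the sign of `r` kept
   aside (positive link = co-occurrence, negative = co-exclusion).
3. **RMT threshold (St)** — scan candidate cutoffs; at each, test the
   nearest-neighbour spacing distribution (NNSD) of the unfolded
   eigenvalues of the thresholded matrix. Noise-dominated matrices follow
   Gaussian-orthogonal-ensemble statistics, `P(d) = (πd/2)·exp(−πd²/4)`;
   modular, system-specific structure follows the Poisson law
   `P(d) = exp(−d)`. St is the smallest cutoff where a chi-square test
   stops rejecting the Poisson law, stably over the next two grid points.
4. **Network & topology** — edges for every pair with `|r| ≥ St`; global
   indices on the unweighted topology: average degree `2E/N`, average path
   distance, average clustering coefficient, harmonic geodesic distance
   `N(N−1)/Σ 1/d_ij`, log–log degree-frequency power-law `R²`, and
   modularity `Q = Σ_s [l_s/E − (d_s/2E)²]` from greedy (CNM) module
   detection.
5. **Node roles (Zi–Pi)** — within-module degree z-score `Zi` and
   participation coefficient `Pi = 1 − Σ_s (k_is/k_i)²`; nodes classify as
   peripherals (`Zi ≤ 2.5, Pi ≤ 0.62`), module hubs (`Zi > 2.5`),
   connectors (`Pi > 0.62`) or network hubs (both). Module hubs and
   connectors are the putative keystone taxa.
6. **Significance** — 100 degree-preserving (double edge swap) random
   networks per empirical network give null mean ± SD per index; networks
   are compared by a Student t-test with those SDs (Welch df).
7. **Clinical association** — Spearman correlation of signed OTU degrees
   (sums of link strengths, split by sign) and keystone abundances against
   tumour-marker values.

A synthetic-data generator (`pmen.simulate`) plants known modular signed
correlation structure, cross-module connector OTUs and marker couplings,
so every stage is testable without access to patient sequencing data.

## Worked example

```python
from pmen import CooccurrenceNetwork, SyntheticSpec, generate_table

spec = SyntheticSpec(groups=("T0",), samples_per_group=40, n_otus=160,
                     module_sizes=(30, 30, 30, 30, 30), rho_within=0.85,
                     rho_between=0.1, sigma=0.25, base_sdlog=0.5, f_neg=0.4,
                     n_connectors=1, anchors_per_module=7, seed=0)
table, truth = generate_table(spec)

model = CooccurrenceNetwork(table, group="T0")
res = model.fit(n_random=100, seed=1)
print(res.summary())
```

```
Co-occurrence network fit [T0]  (St = 0.510)
--------------------------------------------------------
Network size                                   152.000
Total links                                   2230.000
Average degree                                  29.342
Average path distance                            3.207
Average clustering coefficient                   0.957
Average harmonic geodesic distance               2.312
R2 of power-law                                  0.090
Modularity                                       0.778
Module count                                     5.000
Negative link fraction                           0.444
--------------------------------------------------------
Random networks (n = 100, degree-preserving)
Average path distance                     1.817 +/- 0.000
Average clustering coefficient            0.183 +/- 0.002
Average harmonic geodesic distance        1.680 +/- 0.000
Modularity                                0.126 +/- 0.005
```

Reading the output: the scan placed St at 0.51, inside the planted gap
between the background correlation (0.1) and the within-module correlation
(0.85). The five planted modules are recovered exactly (module count 5,
ARI 1.0 against the ground truth), and the planted 40% co-exclusion
fraction appears as a negative-link fraction of 0.444. The empirical
modularity (0.778) towers over its degree-preserving null (0.126 ± 0.005),
i.e. the modular structure is far from a random expectation — the same
comparison logic used for the clinical cohorts. `res.zp` holds the Zi–Pi
table; here the one planted broker OTU is classified as a connector
(`res.keystones()` → `['OTU151']`). The low power-law `R²` is expected for
this dense block-structured toy cohort; sparse real networks score 0.7–0.9.

The same pipeline runs from the shell:

```bash
pmen simulate --seed 17 --out sim/
pmen run sim/otu_table.tsv sim/metadata.tsv --n-random 100 --seed 3 --out run/
pmen report run/ --pairs T0:T5,H:T0
```

`run/` then contains, per group, the filtered table, the threshold scan
trace, edge list + GraphML (Cytoscape/Gephi-ready), node attributes with
Zi–Pi roles, module composition, and the null-ensemble values, plus
cohort-level summary, pairwise t-tests and a checksummed `manifest.json`
that makes the run byte-for-byte reproducible.

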