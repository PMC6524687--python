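"""Synthetic cohort generator: planted structure, determinism, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pmen.association import spearman
from pmen.io import relative_abundance
from pmen.model import CooccurrenceNetwork
from pmen.similarity import pearson_similarity
from pmen.simulate import SyntheticSpec, generate_markers, generate_table

# the strong-signal study conditions used by the recovery suite: 5 planted
# modules of 30 OTUs at rho_w = 0.85 over rho_b = 0.1 background, 40
# replicate samples, one cross-module connector with its anchor members
STRONG = dict(groups=("G",), samples_per_group=40, n_otus=160,
              module_sizes=(30, 30, 30, 30, 30), rho_within=0.85,
              rho_between=0.1, sigma=0.25, base_sdlog=0.5, f_neg=0.4,
              n_connectors=1, anchors_per_module=7)


def _strong(seed, **overrides):
    return SyntheticSpec(seed=seed, **{**STRONG, **overrides})


class TestSpecValidation:
    def test_rho_ordering_enforced(self):
        with pytest.raises(ValueError):
            SyntheticSpec(rho_within=0.2, rho_between=0.5)

    def test_negative_fraction_cap(self):
        with pytest.raises(ValueError, match="0.5"):
            SyntheticSpec(f_neg=0.7)

    def test_module_budget_enforced(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_otus=50, module_sizes=(30, 30))


class TestGenerateTable:
    def test_fixed_seed_bit_identical(self):
        spec = _strong(3)
        a, _ = generate_table(spec)
        b, _ = generate_table(spec)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.otu_ids == b.otu_ids and a.sample_ids == b.sample_ids

    def test_block_structure_separates_within_from_between(self):
        # with no sign flips, mean within-module |r| clearly exceeds between
        gaps = []
        for seed in range(5):
            spec = _strong(seed, f_neg=0.0, n_connectors=0)
            table, truth = generate_table(spec)
            sim = pearson_similarity(relative_abundance(table))
            idx = {o: i for i, o in enumerate(sim.otu_ids)}
            within, between = [], []
            module_otus = [o for o in sim.otu_ids if truth.module_of[o] is not None]
            for a in range(0, len(module_otus), 7):
                for b in range(a + 1, len(module_otus), 5):
                    oa, ob = module_otus[a], module_otus[b]
                    val = sim.sim[idx[oa], idx[ob]]
                    (within if truth.module_of[oa] == truth.module_of[ob]
                     else between).append(val)
            gaps.append(np.mean(within) - np.mean(between))
        assert all(gap > 0.3 for gap in gaps)

    def test_null_structure_has_no_correlation(self):
        spec = SyntheticSpec(groups=("G",), samples_per_group=40, n_otus=60,
                             module_sizes=(), rho_within=0.5, rho_between=0.0,
                             f_neg=0.0, seed=0)
        table, _ = generate_table(spec)
        sim = pearson_similarity(relative_abundance(table))
        off = sim.sim[np.triu_indices(sim.order, k=1)]
        assert off.mean() < 0.2

    def test_group_design_and_depth(self):
        spec = SyntheticSpec(groups=("H", "T0"), samples_per_group=5, n_otus=100,
                             module_sizes=(20,), seed=1)
        table, _ = generate_table(spec)
        assert table.n_samples == 10
        assert table.groups == ["H", "T0"]
        # head-room above the nominal depth so rarefaction keeps most samples
        assert (table.values.sum(axis=0) > 0.9 * spec.target_depth).all()

    def test_planted_negative_couplings_have_negative_sign(self):
        spec = _strong(2, n_connectors=0)
        table, truth = generate_table(spec)
        sim = pearson_similarity(relative_abundance(table))
        idx = {o: i for i, o in enumerate(sim.otu_ids)}
        flipped = [o for o in sim.otu_ids if truth.sign_of[o] == -1
                   and truth.module_of[o] == 0]
        straight = [o for o in sim.otu_ids if truth.sign_of[o] == 1
                    and truth.module_of[o] == 0]
        r = sim.sim[idx[flipped[0]], idx[straight[0]]] * sim.sign[
            idx[flipped[0]], idx[straight[0]]]
        assert r < 0


class TestGenerateMarkers:
    def test_noise_free_negative_coupling_gives_rho_minus_one(self):
        quantity = pd.Series([3.0, 2.5, 2.0, 1.5, 1.0],
                             index=[f"g{i}" for i in range(5)])
        markers = generate_markers(quantity, {"CEA": -2.0}, noise_sd=0.0, seed=0)
        rho, p, _ = spearman(quantity.to_numpy(),
                             markers.values_for("CEA").to_numpy())
        assert rho == pytest.approx(-1.0)

    def test_zero_coupling_is_null(self):
        rng_hits = 0
        quantity = pd.Series(np.linspace(0, 1, 20),
                             index=[f"s{i}" for i in range(20)])
        for seed in range(50):
            markers = generate_markers(quantity, {"CEA": 0.0}, noise_sd=1.0,
                                       seed=seed)
            _, p, _ = spearman(quantity.to_numpy(),
                               markers.values_for("CEA").to_numpy())
            if p > 0.05:
                rng_hits += 1
        assert rng_hits >= 45

    def test_deterministic_under_seed(self):
        quantity = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        a = generate_markers(quantity, {"CEA": 1.0}, noise_sd=0.5, seed=9)
        b = generate_markers(quantity, {"CEA": 1.0}, noise_sd=0.5, seed=9)
        assert a.markers.equals(b.markers)


@pytest.fixture(scope="module")
def fits():
    out = []
    for seed in range(10):
        table, truth = generate_table(_strong(seed))
        res = CooccurrenceNetwork(table, group="G").fit(n_random=0)
        out.append((truth, res))
    return out


class TestEndToEndRecovery:
    """The pipeline run on strong-signal synthetic cohorts must see the truth."""

    def test_modules_recovered(self, fits):
        for truth, res in fits:
            anchors = {a for lst in truth.anchors.values() for a in lst}
            pairs = [(truth.module_of[n], res.partition.membership[n])
                     for n in res.network.nodes
                     if truth.module_of.get(n) is not None and n not in anchors]
            ari = adjusted_rand_score([t for t, _ in pairs], [p for _, p in pairs])
            assert ari >= 0.9

    def test_threshold_inside_planted_gap(self, fits):
        for _, res in fits:
            assert 0.1 < res.st < 0.85

    def test_negative_link_fraction_recovered(self, fits):
        for truth, res in fits:
            assert abs(res.indices.negative_link_fraction - 0.4) <= 0.1

    def test_planted_connector_classified(self, fits):
        # classification of the planted broker is stochastic at 40 samples
        # (see the methods note); it must succeed in a clear majority of seeds
        hits = 0
        for truth, res in fits:
            zp = res.zp.set_index("node")
            for c in truth.connectors:
                if c in zp.index and zp.loc[c, "category"] == "connector":
                    hits += 1
                    break
        assert hits >= 7

    def test_marker_coupling_detected_through_pipeline(self, fits):
        # couple a marker negatively to each seed's mean positive OTU degree
        from pmen.association import otu_degree

        quantities = pd.Series(
            [float(np.mean(list(otu_degree(res.network, "positive").values())))
             for _, res in fits],
            index=[f"seed{i}" for i in range(len(fits))])
        markers = generate_markers(quantities, {"CA199": -1.0}, noise_sd=0.0,
                                   seed=0)
        rho, p, _ = spearman(quantities.to_numpy(),
                             markers.values_for("CA199").to_numpy())
        assert rho < 0 and p < 0.05
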