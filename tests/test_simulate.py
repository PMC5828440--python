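import math

import numpy as np
import pytest

import txclust as tc
from txclust.simulate import DEFAULT_SHIFTS


class TestBuildDesign:
    @pytest.mark.parametrize(
        "category,K,sizes",
        [
            ("TE", 2, (28, 27)),
            ("TE", 3, (18, 18, 19)),
            ("RE", 2, (28, 27)),
            ("TX", 2, (5, 50)),
            ("TX", 3, (5, 17, 33)),
            ("RX", 3, (5, 17, 33)),
        ],
    )
    def test_cluster_sizes(self, category, K, sizes):
        design = tc.build_design(category, K)
        assert design.cluster_sizes == sizes
        assert sum(design.cluster_sizes) == 55

    def test_k1_no_up_fractions(self):
        design = tc.build_design("RE", 1)
        assert design.cluster_sizes == (55,)
        assert design.up_fractions == (0.0,)

    def test_shift_values(self):
        design = tc.build_design("TE", 2)
        dmu1, dmu2, dk1, dk2 = design.shifts
        assert dmu1 == pytest.approx(math.exp(3.375))
        assert dmu2 == pytest.approx(math.exp(5.5))
        assert (dk1, dk2) == (1.01, 1.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tc.build_design("ZZ", 2)
        with pytest.raises(ValueError):
            tc.build_design("TE", 4)


@pytest.fixture
def panel100():
    return tc.GenePanel(tuple(f"g{i:03d}" for i in range(100)), "top_mad")


class TestAssignUpGenes:
    def test_k2_counts(self, panel100):
        design = tc.build_design("TE", 2, base_seed=3)
        sets = tc.assign_up_genes(panel100, design)
        assert set(sets) == {2}
        assert len(sets[2]) == 10

    def test_k3_counts_and_disjoint(self, panel100):
        design = tc.build_design("TE", 3, base_seed=3)
        sets = tc.assign_up_genes(panel100, design)
        assert len(sets[2]) == 10
        assert len(sets[3]) == 20
        assert not sets[2] & sets[3]

    def test_c2_shared_across_k(self, panel100):
        d2 = tc.build_design("TE", 2, base_seed=3)
        d3 = tc.build_design("TE", 3, base_seed=3)
        assert tc.assign_up_genes(panel100, d2)[2] == tc.assign_up_genes(panel100, d3)[2]

    def test_k1_empty(self, panel100):
        design = tc.build_design("TE", 1)
        assert tc.assign_up_genes(panel100, design) == {}

    def test_non_integral_fraction_errors(self):
        panel = tc.GenePanel(tuple(f"g{i}" for i in range(15)), "top_mad")
        design = tc.build_design("TE", 2)
        with pytest.raises(ValueError, match="not integral"):
            tc.assign_up_genes(panel, design)


class TestApplyEffectShifts:
    def test_k1_identity(self, panel_params):
        design = tc.build_design("TE", 1)
        out = tc.apply_effect_shifts(panel_params, design, {})
        assert len(out) == 1
        assert out[0] is panel_params

    def test_shift_arithmetic(self):
        params = tc.NBPanelParams({"g1": tc.NBParams(mu=10.0, k=1.0)})
        design = tc.build_design("TE", 2)
        out = tc.apply_effect_shifts(params, design, {2: frozenset({"g1"})})
        shifted = out[1]["g1"]
        assert shifted.mu == pytest.approx(10 * math.exp(3.375))
        assert shifted.mu == pytest.approx(292.243, abs=0.01)
        assert shifted.k == pytest.approx(1.01)

    def test_c3_uses_second_shift_pair(self):
        params = tc.NBPanelParams({"g1": tc.NBParams(mu=10.0, k=1.0)})
        design = tc.build_design("TE", 3)
        out = tc.apply_effect_shifts(params, design, {3: frozenset({"g1"})})
        assert out[2]["g1"].mu == pytest.approx(10 * math.exp(5.5))
        assert out[2]["g1"].k == pytest.approx(1.03)

    def test_non_up_gene_unchanged(self, panel_params):
        design = tc.build_design("TE", 3, base_seed=1)
        panel = tc.GenePanel(panel_params.gene_ids, "top_mad")
        up = tc.assign_up_genes(panel, design)
        out = tc.apply_effect_shifts(panel_params, design, up)
        untouched = set(panel_params.gene_ids) - up[2] - up[3]
        g = sorted(untouched)[0]
        assert out[1][g] == panel_params[g]
        assert out[2][g] == panel_params[g]

    def test_additive_mode(self):
        params = tc.NBPanelParams({"g1": tc.NBParams(mu=10.0, k=1.0)})
        design = tc.build_design("TE", 2, shift_mode="additive")
        out = tc.apply_effect_shifts(params, design, {2: frozenset({"g1"})})
        assert out[1]["g1"].mu == pytest.approx(10 + math.exp(3.375))
        assert out[1]["g1"].k == pytest.approx(1.0 + 1.01)


class TestSimulateDataset:
    def test_dimensions_and_labels(self, sim_batch_k3):
        design, batch = sim_batch_k3
        ds = batch[0]
        assert ds.counts.counts.shape == (100, 55)
        counts_per_label = np.bincount(ds.true_labels)[1:]
        assert tuple(counts_per_label) == design.cluster_sizes

    def test_determinism(self, panel_params):
        design = tc.build_design("TE", 2, base_seed=9)
        panel = tc.GenePanel(panel_params.gene_ids, "top_mad")
        up = tc.assign_up_genes(panel, design)
        a = tc.simulate_dataset(panel_params, design, up, seed=9)
        b = tc.simulate_dataset(panel_params, design, up, seed=9)
        assert a.counts == b.counts

    def test_mean_recovery_k1(self):
        # 200 replicates of a small panel: empirical mean within 3 MC
        # standard errors of mu for >= 95% of genes
        rng = np.random.default_rng(12)
        gene_ids = tuple(f"g{i}" for i in range(20))
        params = tc.NBPanelParams(
            {
                g: tc.NBParams(mu=float(m), k=float(k))
                for g, m, k in zip(
                    gene_ids,
                    rng.lognormal(3, 1, 20),
                    rng.lognormal(0, 0.5, 20),
                )
            }
        )
        design = tc.build_design("TE", 1, n_datasets=200, base_seed=100)
        batch = tc.simulate_batch(params, design)
        all_counts = np.stack([ds.counts.counts for ds in batch])  # (200,20,55)
        emp_mean = all_counts.mean(axis=(0, 2))
        emp_se = all_counts.std(axis=(0, 2), ddof=1) / np.sqrt(200 * 55)
        mu, _ = params.arrays()
        ok = np.abs(emp_mean - mu) <= 3 * emp_se
        assert ok.mean() >= 0.95

    def test_overdispersion_preserved(self, sim_batch_k3, panel_params):
        _, batch = sim_batch_k3
        counts = batch[0].counts.counts.astype(float)
        mu, k = panel_params.arrays()
        lowk = (k < 1e3) & (mu > 5)
        var = counts.var(axis=1, ddof=1)
        mean = counts.mean(axis=1)
        assert np.mean(var[lowk] > mean[lowk]) > 0.9


class TestSimulateBatch:
    def test_batch_size(self, panel_params):
        design = tc.build_design("RE", 2, n_datasets=4, base_seed=0)
        assert len(tc.simulate_batch(panel_params, design)) == 4

    def test_singleton_matches_simulate_dataset(self, panel_params):
        design = tc.build_design("TE", 2, n_datasets=1, base_seed=21)
        batch = tc.simulate_batch(panel_params, design)
        panel = tc.GenePanel(panel_params.gene_ids, "top_mad")
        up = tc.assign_up_genes(panel, design)
        single = tc.simulate_dataset(panel_params, design, up, seed=21)
        assert batch[0].counts == single.counts

    def test_replicates_differ(self, sim_batch_k3):
        _, batch = sim_batch_k3
        assert batch[0].counts != batch[1].counts

    def test_k1_te_tx_bit_identical(self, panel_params):
        te = tc.build_design("TE", 1, n_datasets=3, base_seed=5)
        tx = tc.build_design("TX", 1, n_datasets=3, base_seed=5)
        for a, b in zip(
            tc.simulate_batch(panel_params, te), tc.simulate_batch(panel_params, tx)
        ):
            assert a.counts == b.counts
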