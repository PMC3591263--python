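import numpy as np
import pytest

from mgforest.association import pairwise_associations
from mgforest.simulate import (SimulationSpec, bxh_spec, make_group_benchmark,
                               planted_partition_network, simulate_bxh,
                               simulate_expression, simulate_f2_genotypes,
                               simulate_phenotype)


def _spec(**kw):
    defaults = dict(n_samples=200, chromosomes=[(5, 0.1)], n_modules=3,
                    genes_per_module=4, rho=0.8, noise_sd=0.5)
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestF2Genotypes:
    def test_no_recombination_gives_identical_columns(self, rng):
        geno = simulate_f2_genotypes(_spec(chromosomes=[(6, 0.0)]), rng)
        for j in range(1, 6):
            np.testing.assert_array_equal(geno.values[:, 0], geno.values[:, j])

    def test_mendelian_frequencies(self, rng):
        geno = simulate_f2_genotypes(_spec(n_samples=5000,
                                           chromosomes=[(2, 0.2)]), rng)
        codes = geno.values[:, 0]
        freqs = [np.mean(codes == c) for c in (0, 1, 2)]
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_free_recombination_decouples_adjacent_markers(self, rng):
        geno = simulate_f2_genotypes(_spec(n_samples=5000,
                                           chromosomes=[(2, 0.5)]), rng)
        A = pairwise_associations(geno)
        assert abs(A.values[0, 1]) < 0.05

    def test_linked_markers_are_associated(self, rng):
        geno = simulate_f2_genotypes(_spec(n_samples=2000,
                                           chromosomes=[(2, 0.02)]), rng)
        A = pairwise_associations(geno)
        assert A.values[0, 1] > 0.5

    def test_invalid_recombination_fraction(self):
        with pytest.raises(ValueError):
            _spec(chromosomes=[(3, 0.7)])

    def test_metadata_has_genomic_positions(self, rng):
        geno = simulate_f2_genotypes(_spec(), rng)
        assert all(v.chromosome is not None for v in geno.variables)
        assert all(v.kind == "categorical" and v.n_levels == 3
                   for v in geno.variables)


class TestExpression:
    def test_within_module_correlation_near_rho(self, rng):
        spec = _spec(n_samples=1000, rho=0.9, genes_per_module=6)
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        block = expr.values[:, :6]
        r = np.corrcoef(block, rowvar=False)
        off = np.abs(r[~np.eye(6, dtype=bool)])
        assert 0.85 <= off.mean() <= 0.95

    def test_between_module_correlation_small(self, rng):
        spec = _spec(n_samples=1000)
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        a = expr.values[:, :4]
        b = expr.values[:, 4:8]
        cross = np.corrcoef(np.hstack([a, b]), rowvar=False)[:4, 4:]
        assert np.abs(cross).mean() < 0.1

    def test_eqtl_drives_gene_marker_association(self, rng):
        spec = _spec(n_samples=2000,
                     eqtl_links=[("chr1_m1", 0, 1.5)])
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        g = geno.column("chr1_m1")
        gene = expr.column("g1_1")
        assert abs(np.corrcoef(g, gene)[0, 1]) > 0.3

    def test_no_eqtl_no_association(self, rng):
        spec = _spec(n_samples=2000)
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        r = np.corrcoef(geno.values[:, 0], expr.values[:, 0])[0, 1]
        assert abs(r) < 0.06


class TestPhenotype:
    def test_noiseless_single_gene_term_is_deterministic(self, rng):
        spec = _spec(additive=[("g1_1", 2.0)], noise_sd=0.0)
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        y, truth = simulate_phenotype(geno, expr, spec, rng)
        r = np.corrcoef(y.values, expr.column("g1_1"))[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert truth.relevant == ["g1_1"]

    def test_interaction_term_has_no_marginal_signal(self, rng):
        spec = _spec(n_samples=4000,
                     interactions=[("g1_1", "g2_1", 2.0)], noise_sd=0.1)
        geno = simulate_f2_genotypes(spec, rng)
        expr = simulate_expression(geno, spec, rng)
        y, _ = simulate_phenotype(geno, expr, spec, rng)
        # centered product: each factor alone is uncorrelated with y
        for g in ("g1_1", "g2_1"):
            assert abs(np.corrcoef(y.values, expr.column(g))[0, 1]) < 0.08
        joint = (expr.column("g1_1") - expr.column("g1_1").mean()) * \
                (expr.column("g2_1") - expr.column("g2_1").mean())
        assert np.corrcoef(y.values, joint)[0, 1] > 0.5

    def test_unknown_term_id_rejected(self, rng):
        spec = _spec(additive=[("nope", 1.0)])
        geno = simulate_f2_genotypes(spec, rng)
        with pytest.raises(ValueError, match="nope"):
            simulate_phenotype(geno, None, spec, rng)

    def test_bxh_defaults_have_marker_and_transcript_terms(self):
        spec = bxh_spec()
        sources = {v for v, _ in spec.additive}
        assert any(v.startswith("chr") for v in sources)
        assert any(v.startswith("g") for v in sources)
        assert spec.interactions


class TestGroupBenchmark:
    def test_relevant_count_is_110(self, rng):
        ds, truth = make_group_benchmark(10, rng)
        assert len(truth.relevant) == 110
        assert all(v in ds.variable_ids for v in truth.relevant)

    def test_noise_variables_have_no_effect(self, rng):
        ds, truth = make_group_benchmark(5, rng)
        noise_ids = [v for v in ds.variable_ids if v.startswith("noise")]
        assert len(noise_ids) >= 1000
        assert not set(noise_ids) & set(truth.relevant)

    def test_g1_pairwise_correlation_in_band(self, rng):
        ds, _ = make_group_benchmark(10, rng, n_samples=500)
        block = ds.values[:, :10]
        r = np.corrcoef(block, rowvar=False)
        off = np.abs(r[~np.eye(10, dtype=bool)])
        assert 0.85 <= off.mean() <= 0.95

    def test_oracle_r2_near_target(self, rng):
        ds, truth = make_group_benchmark(10, rng, n_samples=4000,
                                         target_r2=0.7)
        # regress y on the true signal columns: R^2 should be near target
        y = truth.params["phenotype"]
        Xrel = ds.values[:, :110]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), Xrel]), y, rcond=None)
        pred = np.column_stack([np.ones(len(y)), Xrel]) @ coef
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(0.7, abs=0.07)

    def test_too_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            make_group_benchmark(1, rng)


class TestPlantedPartition:
    def test_zero_out_probability_gives_block_components(self, rng):
        import networkx as nx
        net, labels = planted_partition_network([5, 5], 0.9, 0.0, rng)
        for comp in nx.connected_components(net.graph):
            assert len({labels[v] for v in comp}) == 1

    def test_labels_cover_all_nodes(self, rng):
        net, labels = planted_partition_network([4, 6], 0.5, 0.1, rng)
        assert set(labels) == set(net.node_order)
        assert net.n_nodes == 10

    def test_intra_block_edge_count_near_expectation(self, rng):
        b = 30
        net, labels = planted_partition_network([b], 0.4, 0.01, rng)
        n_pairs = b * (b - 1) // 2
        expected = 0.4 * n_pairs
        sigma = np.sqrt(n_pairs * 0.4 * 0.6)
        assert abs(net.n_edges - expected) <= 3 * sigma

    def test_p_in_must_exceed_p_out(self, rng):
        with pytest.raises(ValueError):
            planted_partition_network([5, 5], 0.1, 0.5, rng)


class TestDeterminism:
    def test_bxh_reproducible_under_seed(self):
        spec = bxh_spec(n_modules=4, genes_per_module=3, n_chromosomes=2)
        a = simulate_bxh(spec, np.random.default_rng(11))
        b = simulate_bxh(spec, np.random.default_rng(11))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        np.testing.assert_array_equal(a[2].values, b[2].values)
        assert a[3].relevant == b[3].relevant

    def test_group_benchmark_reproducible(self):
        a, ta = make_group_benchmark(6, np.random.default_rng(3))
        b, tb = make_group_benchmark(6, np.random.default_rng(3))
        np.testing.assert_array_equal(a.values, b.values)
        assert ta.relevant == tb.relevant
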