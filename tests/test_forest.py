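import numpy as np
import pytest

from mgforest.data import OmicsDataset, PhenotypeVector, VariableDescriptor
from mgforest.forest import (ForestModel, ForestParams, corrected_vi,
                             fit_forest, fit_mgrf, module_importance,
                             oob_error, oob_predict, predict,
                             variable_importance)
from mgforest.modules import ModulePartition
from mgforest.network import CorrelationNetwork

import networkx as nx

from conftest import continuous_dataset, phenotype_for


def _fit(ds, y, **kw):
    params = ForestParams(**{"ntrees": 50, "max_iters": 1, **kw})
    return fit_forest(ds, y, None, None, None, params,
                      np.random.default_rng(0))


class TestFitForest:
    def test_constant_response_gives_stump_forest(self, rng):
        ds = continuous_dataset(rng.normal(size=(30, 3)))
        y = phenotype_for(ds, np.full(30, 7.5))
        model = _fit(ds, y)
        assert all(t.n_nodes == 1 for t in model.trees)
        np.testing.assert_allclose(predict(model, ds), 7.5)

    def test_strong_signal_recovered(self, rng):
        n = 200
        X = rng.normal(size=(n, 6))
        y_val = X[:, 0].copy()
        ds = continuous_dataset(X)
        y = phenotype_for(ds, y_val)
        model = _fit(ds, y, ntrees=200)
        pred = oob_predict(model, ds)
        ss_res = np.sum((pred - y_val) ** 2)
        ss_tot = np.sum((y_val - y_val.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9
        vi = variable_importance(model)
        assert vi["v1"] / sum(vi.values()) > 0.5

    def test_same_seed_gives_identical_forests(self, tiny_dataset):
        ds, y = tiny_dataset
        m1 = _fit(ds, y)
        m2 = _fit(ds, y)
        for t1, t2 in zip(m1.trees, m2.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.threshold, t2.threshold)
            np.testing.assert_array_equal(t1.value, t2.value)
        assert variable_importance(m1) == variable_importance(m2)

    def test_too_few_samples_rejected(self, rng):
        ds = continuous_dataset(rng.normal(size=(4, 2)))
        y = phenotype_for(ds, rng.normal(size=4))
        with pytest.raises(ValueError, match="samples"):
            _fit(ds, y, nodesize=3)

    def test_misaligned_phenotype_rejected(self, rng):
        ds = continuous_dataset(rng.normal(size=(10, 2)))
        y = PhenotypeVector([f"s{i + 2}" for i in range(10)],
                            rng.normal(size=10))
        with pytest.raises(ValueError, match="align"):
            _fit(ds, y)


class TestPredictAndOOB:
    def test_predict_empty_sample_set(self, tiny_dataset):
        ds, y = tiny_dataset
        model = _fit(ds, y)
        empty = ds.select_samples([])
        assert predict(model, empty).shape == (0,)

    def test_predict_unknown_variables_rejected(self, tiny_dataset, rng):
        ds, y = tiny_dataset
        model = _fit(ds, y)
        other = continuous_dataset(rng.normal(size=(3, 2)), prefix="w")
        with pytest.raises(ValueError):
            predict(model, other)

    def test_oob_fraction_matches_bootstrap_expectation(self, rng):
        n = 100
        ds = continuous_dataset(rng.normal(size=(n, 3)))
        y = phenotype_for(ds, rng.normal(size=n))
        model = _fit(ds, y, ntrees=200)
        frac = np.mean([t.oob_idx.size / n for t in model.trees])
        assert frac == pytest.approx((1 - 1 / n) ** n, abs=0.02)

    def test_constant_response_has_zero_oob_rmse(self, rng):
        ds = continuous_dataset(rng.normal(size=(40, 3)))
        y = phenotype_for(ds, np.full(40, 2.0))
        assert oob_error(_fit(ds, y), ds, y) == 0.0

    def test_noise_response_has_larger_oob_error(self, rng):
        n = 120
        X = rng.normal(size=(n, 5))
        ds = continuous_dataset(X)
        informative = phenotype_for(ds, X[:, 0] + 0.2 * rng.normal(size=n))
        noise = phenotype_for(ds, rng.normal(size=n))
        e_info = oob_error(_fit(ds, informative, ntrees=100), ds, informative)
        e_noise = oob_error(_fit(ds, noise, ntrees=100), ds, noise)
        assert e_noise > e_info


class TestImportance:
    def test_unused_variable_has_zero_vi(self, rng):
        n = 80
        X = np.column_stack([rng.normal(size=n), np.zeros(n)])
        ds = continuous_dataset(X)
        y = phenotype_for(ds, X[:, 0])
        vi = variable_importance(_fit(ds, y))
        assert vi["v2"] == 0.0

    def test_vi_conservation_identity(self, tiny_dataset):
        ds, y = tiny_dataset
        model = _fit(ds, y)
        vi = variable_importance(model)
        total_gain = sum(t.gain[t.feature >= 0].sum() for t in model.trees)
        assert sum(vi.values()) * model.ntrees == pytest.approx(total_gain)

    def test_duplicated_column_dilutes_vi(self, rng):
        # the dilution bias cVI corrects: a duplicated informative column
        # splits importance mass, each copy scoring below the lone variable
        n = 150
        x = rng.normal(size=n)
        noise = rng.normal(size=(n, 4))
        y_val = 2 * x + 0.3 * rng.normal(size=n)
        alone = continuous_dataset(np.column_stack([x, noise]))
        dup = continuous_dataset(np.column_stack([x, x + 1e-9, noise]),
                                 prefix="w")
        vi_alone = variable_importance(_fit(alone, phenotype_for(alone, y_val),
                                            ntrees=100))
        vi_dup = variable_importance(_fit(dup, phenotype_for(dup, y_val),
                                          ntrees=100))
        assert vi_dup["w1"] < vi_alone["v1"]
        assert vi_dup["w2"] < vi_alone["v1"]
        assert vi_dup["w1"] + vi_dup["w2"] == pytest.approx(
            vi_alone["v1"], rel=0.35)

    def test_module_importance_sums_member_vis(self):
        part = ModulePartition({"a": 0, "b": 0, "c": 1})
        mi = module_importance({"a": 2.0, "b": 4.0, "c": 1.5}, part)
        assert mi == {0: 6.0, 1: 1.5}

    def test_module_importance_requires_coverage(self):
        part = ModulePartition({"a": 0})
        with pytest.raises(ValueError, match="b"):
            module_importance({"a": 1.0, "b": 2.0}, part)

    def test_mi_total_equals_vi_total(self, rng):
        vi = {f"v{i}": float(rng.random()) for i in range(10)}
        part = ModulePartition({f"v{i}": i % 3 for i in range(10)})
        mi = module_importance(vi, part)
        assert sum(mi.values()) == pytest.approx(sum(vi.values()))


class TestCorrectedVI:
    def _net(self, edges, nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        return CorrelationNetwork(g)

    def test_isolated_variable_keeps_vi(self):
        net = self._net([], ["a"])
        part = ModulePartition({"a": 0})
        assert corrected_vi({"a": 3.0}, part, net) == {"a": 3.0}

    def test_two_member_module_weighted_sum(self):
        net = self._net([("a", "b", 0.5)], ["a", "b"])
        part = ModulePartition({"a": 0, "b": 0})
        cvi = corrected_vi({"a": 2.0, "b": 4.0}, part, net)
        assert cvi == {"a": 2.0 + 0.5 * 4.0, "b": 4.0 + 0.5 * 2.0}

    def test_neighbor_outside_module_does_not_contribute(self):
        net = self._net([("a", "b", 0.9)], ["a", "b"])
        part = ModulePartition({"a": 0, "b": 1})
        cvi = corrected_vi({"a": 2.0, "b": 4.0}, part, net)
        assert cvi == {"a": 2.0, "b": 4.0}

    def test_cvi_at_least_vi(self, rng):
        nodes = [f"v{i}" for i in range(6)]
        edges = [("v0", "v1", 0.7), ("v1", "v2", 0.6), ("v3", "v4", 0.9)]
        net = self._net(edges, nodes)
        part = ModulePartition({v: 0 for v in nodes})
        vi = {v: float(rng.random()) for v in nodes}
        cvi = corrected_vi(vi, part, net)
        assert all(cvi[v] >= vi[v] for v in nodes)


class TestFitMgrf:
    def _setup(self, rng, n=100, m=12):
        X = rng.normal(size=(n, m))
        y_val = 1.5 * X[:, 0] - X[:, 3] + 0.4 * rng.normal(size=n)
        ds = continuous_dataset(X)
        y = phenotype_for(ds, y_val)
        part = ModulePartition.singletons(ds.variable_ids)
        g = nx.Graph()
        g.add_nodes_from(ds.variable_ids)
        net = CorrelationNetwork(g)
        return ds, y, part, net

    def test_percent_importances_sum_to_100(self, rng):
        ds, y, part, net = self._setup(rng)
        params = ForestParams(ntrees=60, max_iters=2)
        _, report, _ = fit_mgrf(ds, y, part, net, params,
                                np.random.default_rng(0))
        assert sum(report.vi_percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(report.mi_percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(report.cvi_percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_weighting_iterations_focus_on_signal(self, rng):
        ds, y, part, net = self._setup(rng)
        params = ForestParams(ntrees=80, max_iters=3, vi_tol=0.0)
        _, report, trace = fit_mgrf(ds, y, part, net, params,
                                    np.random.default_rng(0))
        top2 = sorted(report.vi, key=report.vi.get, reverse=True)[:2]
        assert set(top2) == {"v1", "v4"}
        assert len(trace) == 3
        assert trace[0]["vi_l1_change"] is None
        assert all(t["vi_l1_change"] is not None for t in trace[1:])

    def test_converged_stop_before_max_iters(self, rng):
        ds, y, part, net = self._setup(rng)
        params = ForestParams(ntrees=60, max_iters=8, vi_tol=2.0)
        # an L1 tolerance of 2 (the maximum possible) stops at iteration 1
        _, _, trace = fit_mgrf(ds, y, part, net, params,
                               np.random.default_rng(0))
        assert len(trace) == 2

    def test_deterministic_end_to_end(self, rng):
        ds, y, part, net = self._setup(rng, n=60, m=8)
        params = ForestParams(ntrees=40, max_iters=2)
        r1 = fit_mgrf(ds, y, part, net, params, np.random.default_rng(5))
        r2 = fit_mgrf(ds, y, part, net, params, np.random.default_rng(5))
        assert r1[1].vi == r2[1].vi
        assert r1[1].cvi == r2[1].cvi


def test_forest_model_json_round_trip(tiny_dataset):
    ds, y = tiny_dataset
    model = _fit(ds, y, ntrees=10)
    back = ForestModel.from_json(model.to_json())
    np.testing.assert_allclose(predict(back, ds), predict(model, ds))
    assert back.variable_ids == model.variable_ids
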