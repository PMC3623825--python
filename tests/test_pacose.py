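"""Core graph-constrained estimator tests."""

import numpy as np
import pytest

import pcorsel as pc
from pcorsel.engines import ENGINE_NAMES

from conftest import classical_pcor, truth_pcor


def _model_and_data(p=10, density=0.2, n=400, seed=0):
    g = pc.random_graph(p, "erdos_renyi", density, seed)
    m = pc.build_precision_model(g, seed=seed)
    return m, pc.sample_gaussian(m, n, seed + 1)


class TestNeighborRegression:
    def test_isolated_node_gives_empty_fit(self):
        labels = ("V1", "V2", "V3")
        g = pc.IndependenceGraph(labels, frozenset({("V1", "V2")}))
        rng = np.random.default_rng(0)
        d = pc.Dataset(rng.standard_normal((50, 3)), labels, seed=0)
        fit = pc.fit_neighbor_regression(d, "V3", g, pc.RegressionEngine("ols"))
        assert fit.neighbor_labels == ()
        assert fit.coefficients.shape == (0,)

    def test_chain_matches_population_coefficients(self):
        # oracle: population regression coefficients from the model covariance
        # by the normal equations, Sigma_NN^-1 Sigma_N,target
        labels = ("V1", "V2", "V3")
        chain = pc.IndependenceGraph(labels, frozenset({("V1", "V2"), ("V2", "V3")}))
        m = pc.build_precision_model(chain, seed=21, random_sign=False)
        assert m.graph == chain  # no fill-in possible on this chain orientation
        d = pc.sample_gaussian(m, n=200000, seed=22)
        fit = pc.fit_neighbor_regression(d, "V2", chain, pc.RegressionEngine("ols"))
        cov = np.linalg.inv(m.precision)
        nbrs = [0, 2]
        oracle = np.linalg.solve(cov[np.ix_(nbrs, nbrs)], cov[nbrs, 1])
        assert np.abs(fit.coefficients - oracle).max() < 0.02

    def test_complete_graph_coefficients_equal_scaled_precision_row(self):
        # classical identity: beta_ij = -omega_ij / omega_ii for the inverse
        # sample covariance Omega-hat
        m, d = _model_and_data(p=6, density=0.5, n=500, seed=8)
        complete = pc.IndependenceGraph.complete(d.variable_labels)
        fit = pc.fit_neighbor_regression(d, "V1", complete, pc.RegressionEngine("ols"))
        omega = np.linalg.inv(np.cov(d.values, rowvar=False))
        expected = -omega[0, 1:] / omega[0, 0]
        assert np.allclose(fit.coefficients, expected, atol=1e-8)

    def test_zero_variance_response_rejected(self):
        labels = ("V1", "V2")
        vals = np.column_stack([np.zeros(20), np.random.default_rng(0).standard_normal(20)])
        d = pc.Dataset(vals, labels, seed=0)
        g = pc.IndependenceGraph(labels, frozenset({("V1", "V2")}))
        with pytest.raises(ValueError, match="variance"):
            pc.fit_neighbor_regression(d, "V1", g, pc.RegressionEngine("ols"))


class TestPacose:
    def test_empty_graph_gives_identity(self):
        rng = np.random.default_rng(0)
        labels = tuple(f"V{i+1}" for i in range(5))
        d = pc.Dataset(rng.standard_normal((40, 5)), labels, seed=0)
        est = pc.pacose(d, pc.IndependenceGraph.empty(labels), pc.RegressionEngine("ols"))
        assert np.array_equal(est.values, np.eye(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_complete_graph_ols_equals_inverse_covariance_transform(self, seed):
        m, d = _model_and_data(p=8, density=0.3, n=300, seed=seed)
        complete = pc.IndependenceGraph.complete(d.variable_labels)
        est = pc.pacose(d, complete, pc.RegressionEngine("ols"))
        assert np.abs(est.values - classical_pcor(d)).max() < 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_hard_zeros_and_matrix_invariants(self, seed):
        m, d = _model_and_data(p=12, density=0.2, n=200, seed=seed)
        est = pc.pacose(d, m.graph, pc.RegressionEngine("ols"))
        A = m.graph.adjacency().astype(bool)
        off = ~np.eye(12, dtype=bool)
        assert np.all(est.values[off & ~A] == 0.0)  # literal zeros, not small floats
        assert np.array_equal(est.values, est.values.T)
        assert np.allclose(np.diag(est.values), 1.0)
        assert np.all(np.abs(est.values) <= 1.0)

    def test_consistency_error_shrinks_with_n(self, small_model):
        errs = {}
        for n in (500, 5000):
            reps = []
            for r in range(5):
                d = pc.sample_gaussian(small_model, n, seed=100 + r)
                est = pc.pacose(d, small_model.graph, pc.RegressionEngine("ols"))
                reps.append(np.abs(est.values - small_model.pcor).max())
            errs[n] = np.median(reps)
        assert errs[5000] < errs[500]

    @pytest.mark.parametrize("name", ENGINE_NAMES)
    def test_engine_agnostic_contract(self, name, small_model):
        d = pc.sample_gaussian(small_model, 120, seed=31)
        est = pc.pacose(d, small_model.graph, pc.RegressionEngine(name, cv_folds=5, seed=31))
        A = small_model.graph.adjacency().astype(bool)
        off = ~np.eye(small_model.graph.p, dtype=bool)
        assert np.all(est.values[off & ~A] == 0.0)
        assert np.array_equal(est.values, est.values.T)
        assert np.allclose(np.diag(est.values), 1.0)
        assert np.all(np.abs(est.values) <= 1.0)

    def test_discordant_signs_zeroed(self):
        # under a sparse graph the two regressions defining an edge use
        # different covariate sets, so on pure-noise data their coefficients
        # disagree in sign for roughly half the edges; those entries must come
        # out as exact zeros while remaining edges stay nonzero
        labels = tuple(f"V{i+1}" for i in range(8))
        g = pc.random_graph(8, "erdos_renyi", 0.4, seed=17)
        found = False
        for seed in range(40):
            rng = np.random.default_rng(seed)
            d = pc.Dataset(rng.standard_normal((40, 8)), labels, seed=seed)
            est = pc.pacose(d, g, pc.RegressionEngine("ols"))
            A = g.adjacency().astype(bool)
            if np.any((est.values == 0.0) & A):
                found = True
                break
        assert found, "expected at least one discordant pair across 40 noise draws"

    def test_engine_errors_name_the_node(self):
        rng = np.random.default_rng(0)
        labels = tuple(f"V{i+1}" for i in range(8))
        d = pc.Dataset(rng.standard_normal((6, 8)), labels, seed=0)
        with pytest.raises(RuntimeError, match="V1"):
            pc.pacose(d, pc.IndependenceGraph.complete(labels), pc.RegressionEngine("ols"))

    def test_label_order_canonicalized_to_data(self):
        m, d = _model_and_data(p=6, density=0.4, n=300, seed=4)
        shuffled = m.graph.relabel_order(tuple(reversed(m.graph.node_labels)))
        est = pc.pacose(d, shuffled, pc.RegressionEngine("ols"))
        assert est.variable_labels == d.variable_labels


class TestPrecisionScale:
    def test_identity_round_trip(self):
        labels = ("V1", "V2", "V3")
        eye = pc.PartialCorrelationMatrix(np.eye(3), labels)
        assert np.array_equal(pc.pcor_to_precision_scale(eye, np.ones(3)), np.eye(3))

    def test_reconstructs_true_precision(self, small_model):
        truth = truth_pcor(small_model)
        v = 1.0 / np.diag(small_model.precision)
        rebuilt = pc.pcor_to_precision_scale(truth, v)
        assert np.abs(rebuilt - small_model.precision).max() < 1e-10

    def test_transform_round_trip(self, small_model):
        truth = truth_pcor(small_model)
        v = 1.0 / np.diag(small_model.precision)
        rebuilt = pc.pcor_to_precision_scale(truth, v)
        again = pc.precision_to_pcor(rebuilt, truth.variable_labels)
        assert np.abs(again.values - truth.values).max() < 1e-12

    def test_rejects_nonpositive_variance(self):
        eye = pc.PartialCorrelationMatrix(np.eye(2), ("V1", "V2"))
        with pytest.raises(ValueError, match="positive"):
            pc.pcor_to_precision_scale(eye, np.array([1.0, 0.0]))
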