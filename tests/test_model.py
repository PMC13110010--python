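import numpy as np
import pytest

from spicegcn import (
    GmmGcnRegressor,
    TissueGraph,
    TrainConfig,
    ValidationError,
    gmm_conv,
    kernel_weight,
)
from spicegcn.model import _GraphData
from .conftest import random_graph


def reference_gmm_conv(H, edges, attrs, theta, mu, logvar, aggr="mean"):
    """Explicit double-loop over neighbors and kernels (the defining sum)."""
    n = H.shape[0]
    K, d_out, _ = theta.shape
    out = np.zeros((n, d_out))
    sigma = np.exp(logvar)
    for i in range(n):
        incoming = [(s, a) for (s, d), a in zip(edges.T, attrs) if d == i]
        for j, e in incoming:
            msg = np.zeros(d_out)
            for k in range(K):
                w = np.exp(-0.5 * ((e - mu[k]) ** 2 / sigma[k]).sum())
                msg += w * (theta[k] @ H[j])
            out[i] += msg / K
        if aggr == "mean" and incoming:
            out[i] /= len(incoming)
    return out


class TestKernelWeight:
    def test_unity_at_mean(self):
        assert kernel_weight(np.array([3.0, -1.0]), np.array([3.0, -1.0]),
                             np.array([2.0, 5.0])) == 1.0

    def test_unit_offset_isotropic(self):
        w = kernel_weight(np.array([1.0, 0.0]), np.zeros(2), np.ones(2))
        assert w == pytest.approx(np.exp(-0.5))

    def test_anisotropic_quadratic_form(self):
        # (2,0) under diagonal covariance (4,1): q = 4/4 = 1
        w = kernel_weight(np.array([2.0, 0.0]), np.zeros(2), np.array([4.0, 1.0]))
        assert w == pytest.approx(np.exp(-0.5))

    def test_full_matrix_covariance(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        diff = np.array([0.3, -0.7])
        expected = np.exp(-0.5 * diff @ np.linalg.solve(sigma, diff))
        assert kernel_weight(diff, np.zeros(2), sigma) == pytest.approx(expected)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValidationError):
            kernel_weight(np.zeros(2), np.zeros(2), np.array([1.0, -1.0]))
        with pytest.raises(ValidationError):
            kernel_weight(np.zeros(2), np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGmmConv:
    def test_matches_double_loop_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 11)
            K = rng.integers(1, 4)
            g = random_graph(rng, n, n_features=3, radius=60.0)
            theta = rng.normal(size=(K, 4, 3))
            mu = rng.normal(size=(K, 2))
            logvar = rng.normal(size=(K, 2))
            for aggr in ("mean", "add"):
                fast = gmm_conv(
                    g.features, g.edge_index, g.edge_attr, theta, mu, logvar, aggr=aggr
                )
                slow = reference_gmm_conv(
                    g.features, g.edge_index, g.edge_attr, theta, mu, logvar, aggr=aggr
                )
                assert np.abs(fast - slow).max() <= 1e-6

    def test_isolated_node_gets_zero_vector(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = gmm_conv(
            H, np.zeros((2, 0), dtype=int), np.zeros((0, 2)),
            np.ones((1, 2, 2)), np.zeros((1, 2)), np.zeros((1, 2)),
        )
        np.testing.assert_array_equal(out, np.zeros((2, 2)))

    def test_identity_limit(self):
        # one kernel, huge variance (w ~ 1), identity transform, single neighbor
        H = np.array([[5.0, -2.0], [0.0, 0.0]])
        edges = np.array([[0], [1]])  # message 0 -> 1
        attr = np.array([[1.0, 0.5]])
        out = gmm_conv(
            H, edges, attr,
            theta=np.eye(2)[None], mu=np.zeros((1, 2)), logvar=np.full((1, 2), 40.0),
            aggr="mean",
        )
        np.testing.assert_allclose(out[1], H[0], rtol=1e-9)
        np.testing.assert_array_equal(out[0], 0.0)

    def test_bad_edge_reference_rejected(self):
        with pytest.raises(ValidationError):
            gmm_conv(
                np.zeros((2, 2)), np.array([[0], [5]]), np.zeros((1, 2)),
                np.ones((1, 2, 2)), np.zeros((1, 2)), np.zeros((1, 2)),
            )


def _fit_tiny(graphs, val, **kw):
    kw.setdefault("hidden_dim", 8)
    kw.setdefault("max_epochs", 5)
    kw.setdefault("seed", 0)
    est = GmmGcnRegressor(**kw)
    return est.fit(graphs, validation_graphs=val)


class TestForward:
    def test_r0_predictions_are_per_cell(self):
        """With no edges, each prediction depends only on the cell's own features."""
        rng = np.random.default_rng(1)
        g = random_graph(rng, 12, radius=0.0)
        est = _fit_tiny([g], [g])
        base = est.predict(g)
        perturbed = TissueGraph(
            node_ids=g.node_ids, positions=g.positions,
            features=g.features.copy(), targets=g.targets,
            edge_index=g.edge_index, edge_attr=g.edge_attr, radius=0.0,
            feature_names=g.feature_names, response_names=g.response_names,
        )
        perturbed.features[1:] = rng.normal(size=perturbed.features[1:].shape)
        after = est.predict(perturbed)
        np.testing.assert_array_equal(base[0], after[0])  # bit-identical

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 15, radius=50.0)
        est = _fit_tiny([g], [g], dtype="float64")
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        relabel = inv[g.edge_index]
        order = np.lexsort((relabel[1], relabel[0]))
        gp = TissueGraph(
            node_ids=g.node_ids[perm], positions=g.positions[perm],
            features=g.features[perm], targets=g.targets[perm],
            edge_index=relabel[:, order], edge_attr=g.edge_attr[order],
            radius=g.radius, feature_names=g.feature_names,
            response_names=g.response_names,
        )
        np.testing.assert_allclose(est.predict(gp), est.predict(g)[perm], rtol=1e-10)

    def test_locality_beyond_radius(self):
        """Cells farther than the receptive field cannot affect a prediction."""
        rng = np.random.default_rng(3)
        # two well-separated clusters, radius far below their separation
        pos = np.vstack([rng.uniform(0, 20, (5, 2)), rng.uniform(500, 520, (5, 2))])
        from spicegcn.graphs import compute_edge_attributes, radius_edges

        ei, _ = radius_edges(pos, 25.0)
        attr = compute_edge_attributes(pos, ei)
        g = TissueGraph(
            node_ids=np.arange(10).astype(str), positions=pos,
            features=rng.normal(size=(10, 3)), targets=rng.normal(size=(10, 2)),
            edge_index=ei, edge_attr=attr, radius=25.0,
            feature_names=["a", "b", "c"], response_names=["r0", "r1"],
        )
        est = _fit_tiny([g], [g])
        base = est.predict(g)[:5]
        g.features[5:] = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(est.predict(g)[:5], base)

    def test_feature_width_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        est = _fit_tiny([random_graph(rng, 8)], [random_graph(rng, 8)])
        with pytest.raises(ValidationError, match="features"):
            est.predict(random_graph(rng, 8, n_features=7))


class TestGradients:
    @pytest.mark.parametrize("aggr", ["mean", "add"])
    def test_backward_matches_finite_differences(self, aggr):
        """Analytic gradients of the full network agree with central differences.

        Biases are jittered away from zero so no ReLU pre-activation sits
        exactly on the kink, where two-sided differences are undefined.
        """
        rng = np.random.default_rng(0)
        g = random_graph(rng, 7, n_features=3, n_responses=2, radius=60.0)
        est = GmmGcnRegressor(hidden_dim=4, n_kernels=2, aggr=aggr, dtype="float64", seed=1)
        from spicegcn.model import _GraphData

        params = est._init_params(3, 2, 2, 60.0, np.random.default_rng(1))
        jit = np.random.default_rng(2)
        for key in list(params):
            if key.endswith(".b"):
                params[key] = jit.normal(0.0, 1e-3, size=params[key].shape)
        gd = _GraphData(g)
        _, grads = est._loss_and_grads(params, gd)
        for key, p in params.items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp = est._loss_and_grads(params, gd)[0]
                p[idx] = old - eps
                lm = est._loss_and_grads(params, gd)[0]
                p[idx] = old
                assert abs((lp - lm) / (2 * eps) - grads[key][idx]) < 1e-7, key


class TestTraining:
    def test_learns_identity_map_at_r0(self):
        """Noiseless target = own ligand value is learnable to low MSE."""
        rng = np.random.default_rng(0)
        graphs = []
        for _ in range(6):
            g = random_graph(rng, 80, n_features=2, n_responses=1, radius=0.0)
            g.features = rng.uniform(0, 2, size=g.features.shape)
            g.targets = g.features[:, :1].copy()
            graphs.append(g)
        est = GmmGcnRegressor(hidden_dim=32, max_epochs=200, patience=50, seed=0)
        est.fit(graphs[:4], validation_graphs=graphs[4:5])
        mse = float(((est.predict(graphs[5]) - graphs[5].targets) ** 2).mean())
        assert mse <= 1e-2

    def test_early_stopping_restores_best_epoch(self):
        rng = np.random.default_rng(6)
        train = [random_graph(rng, 30, radius=30.0)]
        val = [random_graph(rng, 30, radius=30.0)]
        est = GmmGcnRegressor(hidden_dim=8, max_epochs=50, patience=1, seed=0)
        est.fit(train, validation_graphs=val)
        h = est.history_
        stop = len(h)
        assert est.best_epoch_ == h["val_mse"].idxmin()
        # stopped one epoch after the last improvement
        assert stop == est.best_epoch_ + 2 or stop == 50

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(7)
        train = [random_graph(rng, 40, radius=40.0) for _ in range(2)]
        val = [random_graph(rng, 40, radius=40.0)]
        a = GmmGcnRegressor(hidden_dim=8, max_epochs=5, seed=3).fit(
            train, validation_graphs=val
        )
        b = GmmGcnRegressor(hidden_dim=8, max_epochs=5, seed=3).fit(
            train, validation_graphs=val
        )
        assert a.history_.equals(b.history_)
        np.testing.assert_array_equal(a.predict(val[0]), b.predict(val[0]))

    def test_requires_validation_graphs(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValidationError):
            GmmGcnRegressor().fit([random_graph(rng, 5)])

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValidationError):
            TrainConfig(patience=0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 25, radius=40.0)
        est = _fit_tiny([g], [g])
        est.save(tmp_path / "model")
        back = GmmGcnRegressor.load(tmp_path / "model")
        np.testing.assert_array_equal(back.predict(g), est.predict(g))

    def test_sklearn_params_round_trip(self):
        est = GmmGcnRegressor(hidden_dim=17, n_kernels=3)
        clone = GmmGcnRegressor(**est.get_params())
        assert clone.get_params() == est.get_params()
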