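import numpy as np
import pytest

from pcabsim.ml import (
    LabelledDataset,
    MolecularGraph,
    MPNNModel,
    clapp_from_vss_halflife,
    fup_from_ppbr,
    gika_from_papp,
    kfold_best_model,
    m5p_fit,
    m5p_predict,
    mpnn_forward,
)
from pcabsim.ml.graphs import GraphError
from pcabsim.ml.selection import mean_absolute_error
from pcabsim.synth import generate_regression_data


def _random_graph(n_nodes=8, node_dim=5, edge_dim=3, seed=0):
    rng = np.random.default_rng(seed)
    edges = []
    for v in range(1, n_nodes):  # spanning tree + extras
        edges.append((rng.integers(0, v), v))
    edges.append((0, n_nodes - 1))
    return MolecularGraph(
        node_features=rng.normal(size=(n_nodes, node_dim)),
        edges=tuple((int(a), int(b)) for a, b in edges),
        edge_features=rng.normal(size=(len(edges), edge_dim)),
    )


class TestMPNN:
    def test_single_node_no_edges_identity_readout(self):
        g = MolecularGraph(node_features=np.array([[1.0, 2.0]]), edges=())
        model = MPNNModel(
            n_steps=0,
            w_in=np.eye(2),
            readout_fn=lambda h: h.sum(),
        )
        assert mpnn_forward(g, model) == pytest.approx(3.0)

    def test_two_node_path_hand_computed(self):
        # identity input projection, message = h_w (identity), update h+m,
        # sum readout with unit weights, T=1:
        # h0 = [[1,0],[0,2]]; after one step h = [[1,2],[1,2]]; sum = [2,4]
        g = MolecularGraph(node_features=np.array([[1.0, 0.0], [0.0, 2.0]]), edges=((0, 1),))
        model = MPNNModel(
            n_steps=1,
            w_in=np.eye(2),
            w_msg_h=np.eye(2),
            w_msg_e=None,
            w_out=np.ones(2),
            b_out=0.0,
        )
        assert mpnn_forward(g, model) == pytest.approx(6.0)

    def test_permutation_invariance_100_relabelings(self):
        g = _random_graph(seed=1)
        model = MPNNModel.random(node_dim=5, edge_dim=3, hidden_dim=8, n_steps=3, seed=2)
        ref = mpnn_forward(g, model)
        rng = np.random.default_rng(3)
        for _ in range(100):
            perm = rng.permutation(g.n_nodes)
            assert mpnn_forward(g.relabel(perm), model) == pytest.approx(ref, abs=1e-10)

    def test_edge_list_reordering_invariance(self):
        g = _random_graph(seed=4)
        model = MPNNModel.random(node_dim=5, edge_dim=3, seed=5)
        ref = mpnn_forward(g, model)
        rng = np.random.default_rng(6)
        order = rng.permutation(len(g.edges))
        g2 = MolecularGraph(
            node_features=g.node_features,
            edges=tuple(g.edges[i] for i in order),
            edge_features=g.edge_features[order],
        )
        assert mpnn_forward(g2, model) == pytest.approx(ref, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        g = _random_graph(node_dim=4)
        model = MPNNModel.random(node_dim=5, edge_dim=3)
        with pytest.raises(ValueError):
            mpnn_forward(g, model)

    def test_self_loop_rejected(self):
        with pytest.raises(GraphError, match="self-loop"):
            MolecularGraph(node_features=np.zeros((2, 1)), edges=((1, 1),))


class TestModelTree:
    def test_noiseless_linear_recovered_exactly(self):
        data = generate_regression_data("linear", n=200, noise_sd=0.0, seed=1)
        ens = m5p_fit(data.inputs, data.targets, n_trees=5, seed=1)
        pred = m5p_predict(ens, data.inputs)
        assert mean_absolute_error(data.targets, pred) < 1e-6

    def test_constant_target_predicts_constant(self):
        X = np.linspace(-1, 1, 50).reshape(-1, 1)
        y = np.full(50, 3.5)
        ens = m5p_fit(X, y, n_trees=3, seed=0)
        assert np.allclose(m5p_predict(ens, X), 3.5, atol=1e-9)
        # degenerate data must give single-leaf trees, not an error
        assert all(t.root.is_leaf for t in ens.trees)

    def test_piecewise_beats_constant_baseline(self):
        train = generate_regression_data("piecewise", n=500, noise_sd=0.05, seed=42)
        test = generate_regression_data("piecewise", n=500, noise_sd=0.0, seed=43)
        ens = m5p_fit(train.inputs, train.targets, n_trees=20, seed=42)
        mae = mean_absolute_error(test.targets, m5p_predict(ens, test.inputs))
        baseline = mean_absolute_error(
            test.targets, np.full(len(test), train.targets.mean())
        )
        assert mae < 0.25 * baseline

    def test_seeded_bit_reproducibility(self):
        data = generate_regression_data("friedman", n=300, noise_sd=0.5, seed=9)
        grid = generate_regression_data("friedman", n=100, noise_sd=0.0, seed=10)
        p1 = m5p_predict(m5p_fit(data.inputs, data.targets, n_trees=10, seed=7), grid.inputs)
        p2 = m5p_predict(m5p_fit(data.inputs, data.targets, n_trees=10, seed=7), grid.inputs)
        assert np.array_equal(p1, p2)

    def test_prediction_is_tree_average(self):
        data = generate_regression_data("piecewise", n=100, noise_sd=0.1, seed=2)
        ens = m5p_fit(data.inputs, data.targets, n_trees=4, seed=2)
        x = np.array([[0.3]])
        per_tree = [t.predict(x)[0] for t in ens.trees]
        assert ens.predict(x)[0] == pytest.approx(np.mean(per_tree), rel=1e-12)

    def test_feature_dimension_mismatch_rejected(self):
        data = generate_regression_data("linear", n=50, seed=0)
        ens = m5p_fit(data.inputs, data.targets, n_trees=2, seed=0)
        with pytest.raises(ValueError, match="features"):
            ens.predict(np.zeros((3, 4)))

    def test_more_trees_do_not_increase_heldout_variance(self):
        train = generate_regression_data("friedman", n=400, noise_sd=1.0, seed=20)
        test = generate_regression_data("friedman", n=200, noise_sd=0.0, seed=21)
        preds = {}
        for n_trees in (2, 40):
            errs = []
            for seed in range(5):
                ens = m5p_fit(
                    train.inputs, train.targets, n_trees=n_trees,
                    sample_fraction=0.7, seed=seed,
                )
                errs.append(m5p_predict(ens, test.inputs))
            preds[n_trees] = np.var(np.stack(errs), axis=0).mean()
        assert preds[40] <= preds[2]


class TestKFold:
    def _fit(self, X, y):
        return m5p_fit(X, y, n_trees=3, seed=0)

    def test_folds_partition_every_index_once(self):
        data = generate_regression_data("linear", n=57, noise_sd=0.1, seed=3)
        seen = []
        _, table = kfold_best_model(data, self._fit, m5p_predict, k=10, seed=5)
        assert len(table) == 10
        # fold sizes differ by at most one
        rng = np.random.default_rng(5)
        order = rng.permutation(57)
        folds = np.array_split(order, 10)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(57))

    def test_best_model_is_mae_argmin(self):
        data = generate_regression_data("piecewise", n=120, noise_sd=0.2, seed=4)
        best, table = kfold_best_model(data, self._fit, m5p_predict, k=10, seed=6)
        assert table["mae"].min() == table.loc[table["mae"].idxmin(), "mae"]
        assert table["mae"].min() <= table["mae"].mean()
        assert {"fold", "mae", "r_squared"} <= set(table.columns)

    def test_split_deterministic_from_seed(self):
        data = generate_regression_data("linear", n=80, noise_sd=0.3, seed=8)
        _, t1 = kfold_best_model(data, self._fit, m5p_predict, k=5, seed=9)
        _, t2 = kfold_best_model(data, self._fit, m5p_predict, k=5, seed=9)
        assert t1.equals(t2)

    def test_k_larger_than_n_rejected(self):
        data = generate_regression_data("linear", n=10, seed=0)
        with pytest.raises(ValueError):
            kfold_best_model(data, self._fit, m5p_predict, k=11)


class TestDerivedADME:
    @pytest.mark.parametrize(
        "ppbr, fup", [(0.86582, 0.13418), (0.0, 1.0), (0.5, 0.5)]
    )
    def test_fup_from_ppbr(self, ppbr, fup):
        assert fup_from_ppbr(ppbr) == pytest.approx(fup)

    def test_clapp_from_vss_halflife(self):
        assert clapp_from_vss_halflife(1.0, 0.693) == pytest.approx(1.0)
        assert clapp_from_vss_halflife(100.0, 6.93) == pytest.approx(10.0)
        assert clapp_from_vss_halflife(2.0, 5.0) == pytest.approx(
            2 * clapp_from_vss_halflife(1.0, 5.0)
        )

    def test_gika_from_papp(self):
        assert gika_from_papp(1.25, 1.25) == pytest.approx(2.0)
        assert gika_from_papp(0.948, 1.25) == pytest.approx(1.5168, abs=5e-4)
        assert gika_from_papp(1.0, 2.5) == pytest.approx(gika_from_papp(1.0, 1.25) / 2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fup_from_ppbr(1.0)
        with pytest.raises(ValueError):
            clapp_from_vss_halflife(0.0, 1.0)
        with pytest.raises(ValueError):
            gika_from_papp(-1.0)
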