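import numpy as np
import pytest

from hiermap.graphio import LevelGraph, partition_from_components
from hiermap.hilander import (
    LabelPartition,
    LinkageScores,
    ModelConfig,
    TrainedModel,
    _forward,
    _heads,
    _loss_and_grads,
    aggregate_level,
    decode_level,
    flatten_go_labels,
    ground_truth_targets,
    infer_hierarchy,
    init_model,
    mpgnn_encode,
    oracle_scorer,
    score_graph,
    split_nodes,
    train_model,
)
from hiermap.simulate import SyntheticSpec, simulate_dataset

from conftest import make_graph


# ---------------------------------------------------------------------------
# label flattening and splits
# ---------------------------------------------------------------------------


class TestFlattenGoLabels:
    def _annotations(self):
        ann = {}
        # term small: 30 genes; term big: 200 genes; term tiny: 3 genes
        for i in range(200):
            ann[f"g{i}"] = {"big"}
        for i in range(30):
            ann[f"g{i}"].add("small")
        for i in range(3):
            ann[f"g{i}"].add("tiny")
        return ann

    def test_smallest_surviving_term_wins(self):
        part = flatten_go_labels(self._annotations(), min_size=10, max_size=500)
        assert part.assignments["g0"] == "small"  # tiny filtered, small < big
        assert part.assignments["g100"] == "big"

    def test_gene_without_qualifying_term_excluded(self):
        ann = self._annotations()
        ann["lonely"] = {"tiny"}
        part = flatten_go_labels(ann, min_size=10, max_size=500)
        assert "lonely" not in part.assignments

    def test_single_shared_term(self):
        ann = {f"g{i}": {"only"} for i in range(20)}
        part = flatten_go_labels(ann, min_size=10, max_size=500)
        assert set(part.assignments.values()) == {"only"}

    def test_no_surviving_term_raises(self):
        with pytest.raises(ValueError, match="widen"):
            flatten_go_labels({"g1": {"t"}}, min_size=10, max_size=500)

    def test_class_sizes(self):
        part = flatten_go_labels(self._annotations(), min_size=10, max_size=500)
        assert part.class_sizes["small"] == 30
        assert part.class_sizes["big"] == 170


class TestSplitNodes:
    def test_sizes_70_10_20(self):
        ids = [f"n{i}" for i in range(100)]
        train, val, test = split_nodes(ids, (0.7, 0.1, 0.2), seed=0)
        assert (len(train), len(val), len(test)) == (70, 10, 20)

    def test_deterministic(self):
        ids = [f"n{i}" for i in range(53)]
        assert split_nodes(ids, seed=4) == split_nodes(ids, seed=4)

    def test_partition_property(self):
        ids = [f"n{i}" for i in range(37)]
        train, val, test = split_nodes(ids, seed=1)
        assert train | val | test == set(ids)
        assert not (train & val or train & test or val & test)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            split_nodes(["a", "b"], seed=0)

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            split_nodes(list("abcdef"), (0.5, 0.2, 0.2), seed=0)


# ---------------------------------------------------------------------------
# encoder forward pass
# ---------------------------------------------------------------------------


class TestMpgnnEncode:
    def test_zero_layers_is_input_projection(self):
        g = make_graph(4, [(0, 1), (1, 2)], dim=3, seed=1)
        cfg = ModelConfig(mpgnn_layers=0, hidden_dim=5, epochs=0)
        model = init_model(cfg, 3)
        H = mpgnn_encode(g, model)
        expected = np.maximum(
            g.node_features @ model.base["W_in"] + model.base["b_in"], 0.0
        )
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_isolated_node_ignores_others(self):
        # perturbation oracle: node 3 has no edges; changing other features
        # must not move its embedding
        edges = [(0, 1), (1, 2)]
        g1 = make_graph(4, edges, dim=3, seed=2)
        feats = np.array(g1.node_features)
        feats[:3] += 10.0
        g2 = LevelGraph(
            level=0,
            node_ids=g1.node_ids,
            node_features=feats,
            edges=g1.edges,
            edge_attr=g1.edge_attr,
        )
        model = init_model(ModelConfig(hidden_dim=6, epochs=0), 3)
        H1, H2 = mpgnn_encode(g1, model), mpgnn_encode(g2, model)
        np.testing.assert_allclose(H1[3], H2[3], atol=1e-12)
        assert not np.allclose(H1[0], H2[0])

    def test_width_mismatch_raises(self):
        g = make_graph(3, [(0, 1)], dim=4)
        model = init_model(ModelConfig(epochs=0), 7)
        with pytest.raises(ValueError, match="width"):
            mpgnn_encode(g, model)

    def test_three_node_path_hand_computation(self):
        # one layer, hand-set weights, unit channel scores; expected values
        # computed with explicit per-node loops
        n, d, h = 3, 2, 2
        ids = ("a", "b", "c")
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        edges = np.array([[0, 1], [1, 2]])
        attr = np.ones((2, 5))
        g = LevelGraph(level=0, node_ids=ids, node_features=X, edges=edges, edge_attr=attr)
        cfg = ModelConfig(mpgnn_layers=1, hidden_dim=h, epochs=0)
        model = init_model(cfg, d)
        p = model.base
        p["W_in"] = np.eye(d)
        p["b_in"] = np.zeros(h)
        p["W_msg0"] = np.ones((2 * h + 5, h))
        p["b_msg0"] = np.zeros(h)
        p["W_upd0"] = np.vstack([np.eye(h), np.eye(h)])
        p["b_upd0"] = np.zeros(h)

        H = mpgnn_encode(g, model)

        # hand computation: H0 = X (identity projection, all nonnegative)
        H0 = X.copy()
        neighbors = {0: [1], 1: [0, 2], 2: [1]}
        expected = np.zeros((n, h))
        for i in range(n):
            msgs = []
            for j in neighbors[i]:
                pre = np.concatenate([H0[j], H0[i], np.ones(5)])  # message j -> i
                msgs.append(np.maximum(pre @ p["W_msg0"], 0.0))
            agg = np.mean(msgs, axis=0)
            expected[i] = np.maximum(H0[i] + agg, 0.0)  # W_upd = [I; I]
        np.testing.assert_allclose(H, expected, atol=1e-12)


class TestGradients:
    def test_finite_difference_check(self):
        rng = np.random.default_rng(0)
        g = make_graph(6, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)], dim=3, seed=3)
        cfg = ModelConfig(mpgnn_layers=2, hidden_dim=4, epochs=0)
        model = init_model(cfg, 3)
        params = model.base
        edge_t = rng.integers(0, 2, g.n_edges).astype(float)
        dens_t = rng.uniform(-1, 1, g.n_nodes)
        e_mask = np.ones(g.n_edges)
        n_mask = np.ones(g.n_nodes)

        def loss_of(p):
            cache = _forward(p, g.node_features, g.edges, g.edge_attr, cfg.mpgnn_layers)
            _, _, hc = _heads(p, cache["H_final"], g.edges)
            val, _ = _loss_and_grads(
                p, cache, hc, g.edges, edge_t, dens_t, e_mask, n_mask,
                cfg.loss_weights, cfg.mpgnn_layers,
            )
            return val

        base_loss = loss_of(params)
        cache = _forward(params, g.node_features, g.edges, g.edge_attr, cfg.mpgnn_layers)
        _, _, hc = _heads(params, cache["H_final"], g.edges)
        _, grads = _loss_and_grads(
            params, cache, hc, g.edges, edge_t, dens_t, e_mask, n_mask,
            cfg.loss_weights, cfg.mpgnn_layers,
        )
        eps = 1e-6
        checked = 0
        for key in sorted(params):
            flat = params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_of(params)
                flat[idx] = orig - eps
                down = loss_of(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=1e-5), key
                checked += 1
        assert checked > 20
        assert loss_of(params) == base_loss


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------


class TestGroundTruthTargets:
    def test_uniform_neighborhood_density_one(self):
        g = make_graph(3, [(0, 1), (0, 2)], channels=np.ones((2, 5)))
        labels = {"n00": "A", "n01": "A", "n02": "A"}
        t = ground_truth_targets(g, labels)
        assert t.density_target[0] == 1.0
        np.testing.assert_array_equal(t.edge_target, [1.0, 1.0])

    def test_neighborless_density_zero(self):
        g = make_graph(3, [(0, 1)])
        labels = {f"n{i:02d}": "A" for i in range(3)}
        t = ground_truth_targets(g, labels)
        assert t.density_target[2] == 0.0

    def test_mixed_labels_hand_computation(self):
        # 4-node star around n00 with unit weights, labels A A B B
        g = make_graph(4, [(0, 1), (0, 2), (0, 3)], channels=np.ones((3, 5)))
        labels = {"n00": "A", "n01": "A", "n02": "B", "n03": "B"}
        t = ground_truth_targets(g, labels)
        # hand: node 0 sees +1, -1, -1 with equal weight -> -1/3
        assert t.density_target[0] == pytest.approx(-1 / 3)
        assert t.density_target[1] == 1.0
        assert t.density_target[2] == -1.0
        np.testing.assert_array_equal(t.edge_target, [1.0, 0.0, 0.0])

    def test_unlabeled_nodes_masked(self):
        g = make_graph(3, [(0, 1), (1, 2)])
        t = ground_truth_targets(g, {"n00": "A", "n01": "A"})
        assert t.node_mask.tolist() == [1.0, 1.0, 0.0]
        assert t.edge_mask.tolist() == [1.0, 0.0]


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _scores(graph, probs, densities):
    return LinkageScores(
        edge_prob=np.asarray(probs, dtype=float),
        node_density=np.asarray(densities, dtype=float),
    )


class TestDecodeLevel:
    def test_spec_example(self):
        # path 1-2-3-4 with given probs/densities -> clusters {1,2},{3,4}
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)])
        scores = _scores(g, [0.9, 0.4, 0.8], [0.1, 0.5, 0.2, 0.6])
        parts = partition_from_components(decode_level(g, scores, 0.5))
        assert set(map(frozenset, parts.values())) == {
            frozenset({"n00", "n01"}),
            frozenset({"n02", "n03"}),
        }

    def test_tau_above_all_gives_singletons(self):
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)])
        scores = _scores(g, [0.3, 0.3, 0.3], [0.1, 0.2, 0.3, 0.4])
        parts = partition_from_components(decode_level(g, scores, 0.5))
        assert len(parts) == 4

    def test_monotone_densities_on_path_one_cluster(self):
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)])
        scores = _scores(g, [1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.4])
        parts = partition_from_components(decode_level(g, scores, 0.5))
        assert len(parts) == 1

    def test_tie_broken_by_smaller_node_id(self):
        # node 1 sees nodes 0 and 2 at identical prob/density
        g = make_graph(3, [(0, 1), (1, 2)])
        scores = _scores(g, [0.9, 0.9], [0.5, 0.1, 0.5])
        assignment = decode_level(g, scores, 0.5)
        assert assignment["n01"] == assignment["n00"]
        assert assignment["n02"] != assignment["n01"]

    def test_refines_as_tau_rises(self):
        rng = np.random.default_rng(7)
        g = make_graph(20, [(a, b) for a in range(20) for b in range(a + 1, 20) if rng.random() < 0.2], seed=7)
        scores = _scores(g, rng.random(g.n_edges), rng.uniform(-1, 1, g.n_nodes))
        previous = None
        for tau in (0.0, 0.3, 0.6, 0.9, 1.01):
            assignment = decode_level(g, scores, tau)
            parts = partition_from_components(assignment)
            if previous is not None:
                # raising tau never merges previously separate clusters
                assert len(parts) >= len(previous)
                for members in parts.values():
                    host = {previous_assignment[m] for m in members}
                    assert len(host) == 1 or all(len(parts[c]) for c in host)
                    # every new cluster sits inside one old cluster
                    assert len({previous_assignment[m] for m in members}) == 1
            previous = parts
            previous_assignment = assignment

    def test_always_partition(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            rng2 = np.random.default_rng(seed)
            n = int(rng2.integers(3, 25))
            edges = [(a, b) for a in range(n) for b in range(a + 1, n) if rng2.random() < 0.3]
            g = make_graph(n, edges, seed=seed)
            scores = _scores(g, rng2.random(g.n_edges), rng2.uniform(-1, 1, n))
            assignment = decode_level(g, scores, 0.5)
            assert set(assignment) == set(g.node_ids)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


class TestAggregateLevel:
    def test_all_singletons_count_unchanged(self):
        g = make_graph(5, [(0, 1), (2, 3)])
        scores = _scores(g, [0.0, 0.0], np.zeros(5))
        clusters = {nid: {nid} for nid in g.node_ids}
        nxt = aggregate_level(g, clusters, scores)
        assert nxt.n_nodes == 5
        assert nxt.level == 1
        assert set(nxt.node_ids) == set(g.node_ids)

    def test_mean_and_peak_features(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        g = LevelGraph(
            level=0, node_ids=("a", "b"), node_features=X,
            edges=np.array([[0, 1]]), edge_attr=np.ones((1, 5)),
        )
        scores = _scores(g, [1.0], [0.1, 0.9])  # b is the density peak
        nxt = aggregate_level(g, {"a": {"a", "b"}}, scores)
        np.testing.assert_allclose(nxt.node_features[0], [0.5, 0.5])
        np.testing.assert_allclose(nxt.peak_features[0], [0.0, 1.0])
        assert nxt.members["a"] == frozenset({"a", "b"})

    def test_single_cluster_terminates(self):
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)])
        scores = _scores(g, np.ones(3), np.zeros(4))
        nxt = aggregate_level(g, {"all": set(g.node_ids)}, scores)
        assert nxt.n_nodes == 1 and nxt.n_edges == 0

    def test_gene_mass_conserved(self):
        g = make_graph(6, [(0, 1), (2, 3), (4, 5)])
        scores = _scores(g, np.ones(3), np.zeros(6))
        clusters = {
            "c1": {"n00", "n01"},
            "c2": {"n02", "n03"},
            "c3": {"n04", "n05"},
        }
        nxt = aggregate_level(g, clusters, scores)
        assert nxt.n_nodes == len(clusters)
        assert sum(len(m) for m in nxt.members.values()) == g.n_nodes

    def test_non_partition_rejected(self):
        g = make_graph(3, [(0, 1)])
        scores = _scores(g, [1.0], np.zeros(3))
        with pytest.raises(ValueError):
            aggregate_level(g, {"c": {"n00"}}, scores)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _easy_dataset(seed=0):
    return simulate_dataset(
        SyntheticSpec(n_genes=120, branching=(8, 2), feature_dim=12, seed=seed)
    )


class TestTrainModel:
    def test_epochs_zero_returns_initialization(self):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=8, epochs=0)
        split = split_nodes(ds.graph.node_ids, seed=0)
        model = train_model(ds.graph, ds.labels, split, cfg)
        reference = init_model(cfg, ds.graph.node_features.shape[1])
        for key in reference.base:
            np.testing.assert_array_equal(model.base[key], reference.base[key])

    def test_loss_decreases(self):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=16, epochs=25, seed=0)
        split = split_nodes(ds.graph.node_ids, seed=0)
        model = train_model(ds.graph, ds.labels, split, cfg)
        base = [h for h in model.history if h["phase"] == "base"]
        assert base[-1]["loss"] <= base[0]["loss"]

    def test_validation_fp_high_on_easy_data(self):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=32, epochs=40, seed=0)
        split = split_nodes(ds.graph.node_ids, seed=0)
        model = train_model(ds.graph, ds.labels, split, cfg)
        base = [h for h in model.history if h["phase"] == "base"]
        assert base[-1]["val_fp"] >= 0.9

    def test_deterministic_given_seed(self):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=8, epochs=5, seed=3)
        split = split_nodes(ds.graph.node_ids, seed=3)
        m1 = train_model(ds.graph, ds.labels, split, cfg)
        m2 = train_model(ds.graph, ds.labels, split, cfg)
        for key in m1.base:
            np.testing.assert_array_equal(m1.base[key], m2.base[key])

    def test_empty_training_edges_raises(self):
        g = make_graph(5, [(3, 4)])
        labels = LabelPartition({f"n{i:02d}": "A" for i in range(5)})
        with pytest.raises(ValueError, match="edge"):
            train_model(g, labels, ({"n00", "n01"}, {"n02"}, {"n03", "n04"}),
                        ModelConfig(hidden_dim=4, epochs=1))

    def test_save_load_bit_exact(self, tmp_path):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=8, epochs=3, seed=0)
        split = split_nodes(ds.graph.node_ids, seed=0)
        model = train_model(ds.graph, ds.labels, split, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        back = TrainedModel.load(path)
        assert back.config == model.config
        for key in model.base:
            np.testing.assert_array_equal(back.base[key], model.base[key])
        for key in model.upper:
            np.testing.assert_array_equal(back.upper[key], model.upper[key])


# ---------------------------------------------------------------------------
# hierarchy inference
# ---------------------------------------------------------------------------


class TestInferHierarchy:
    def test_no_scores_above_tau_gives_zero_systems(self):
        ds = _easy_dataset()
        cfg = ModelConfig(hidden_dim=8, epochs=0, p_tau=1.0)
        scorer = lambda g: LinkageScores(  # noqa: E731
            edge_prob=np.full(g.n_edges, 0.5), node_density=np.zeros(g.n_nodes)
        )
        hier = infer_hierarchy(ds.graph, None, cfg, scorer=scorer)
        assert len(hier.children) == 0
        assert set(hier.genes) == set(ds.graph.node_ids)

    def test_max_levels_one(self):
        ds = _easy_dataset()
        scorer = oracle_scorer([ds.partition_at(1), ds.partition_at(2)])
        cfg = ModelConfig(hidden_dim=8, epochs=0, max_levels=1)
        hier = infer_hierarchy(ds.graph, None, cfg, scorer=scorer)
        assert hier.max_level() <= 1

    def test_oracle_recovery_exact(self):
        from hiermap.clustereval import evaluate_hierarchy_level

        ds = simulate_dataset(
            SyntheticSpec(n_genes=120, branching=(8, 2), feature_dim=12, p_in=1.0, seed=1)
        )
        scorer = oracle_scorer([ds.partition_at(1), ds.partition_at(2)])
        cfg = ModelConfig(hidden_dim=8, epochs=0)
        hier = infer_hierarchy(ds.graph, None, cfg, scorer=scorer)
        for level in (1, 2):
            rep = evaluate_hierarchy_level(
                hier, LabelPartition(ds.partition_at(level)), level
            )
            assert rep.fp == 1.0

    def test_gene_mass_and_single_parent(self):
        ds = _easy_dataset(seed=2)
        scorer = oracle_scorer([ds.partition_at(1), ds.partition_at(2)])
        hier = infer_hierarchy(ds.graph, None, ModelConfig(hidden_dim=8, epochs=0), scorer=scorer)
        hier.validate()
        parents = hier.parent_map()
        for gene in hier.genes:
            chain = set()
            node = gene
            while node in parents:
                node = parents[node]
                assert node not in chain
                chain.add(node)

    def test_deterministic(self):
        ds = _easy_dataset(seed=5)
        cfg = ModelConfig(hidden_dim=8, epochs=4, seed=5)
        split = split_nodes(ds.graph.node_ids, seed=5)
        model = train_model(ds.graph, ds.labels, split, cfg)
        h1 = infer_hierarchy(ds.graph, model)
        h2 = infer_hierarchy(ds.graph, model)
        assert h1 == h2
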