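"""Traversal model: activation rule, distances, ranks, embeddings."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from flybrain import flow as fl
from flybrain.synthetic import generate_layered_network
from _oracles import traversal_expectations


def edge_df(triples):
    return pd.DataFrame(triples, columns=["pre_root_id", "post_root_id", "syn_count"])


class TestActivation:
    def test_linear_below_saturation(self):
        # f = 0.15 at tau = 0.3 gives probability 0.5
        assert fl.traversal_probability(0.15, 0.3) == pytest.approx(0.5)
        assert fl.traversal_probability(0.0, 0.3) == 0.0

    def test_saturates_at_tau(self):
        assert fl.traversal_probability(0.3, 0.3) == 1.0
        assert fl.traversal_probability(0.9, 0.3) == 1.0

    def test_monotone_in_input_fraction(self):
        f = np.linspace(0, 1, 101)
        p = fl.traversal_probability(f, 0.3)
        assert (np.diff(p) >= 0).all()


class TestTraversalRun:
    def test_chain_is_deterministic(self):
        edges = edge_df([(1, 2, 10), (2, 3, 10)])
        for run in range(5):
            d = fl.traversal_run(edges, {1}, run_index=run)
            assert d == {1: 0.0, 2: 1.0, 3: 2.0}

    def test_deterministic_given_seed_and_run_index(self):
        edges = edge_df([(1, 2, 2), (2, 2, 8), (1, 3, 1), (3, 3, 9)])
        cfg = fl.TraversalConfig(rng_seed=42)
        a = fl.traversal_run(edges, {1}, cfg, run_index=3)
        b = fl.traversal_run(edges, {1}, cfg, run_index=3)
        assert a == b

    def test_empty_seed_set_raises(self):
        with pytest.raises(ValueError, match="no seeds"):
            fl.traversal_run(edge_df([(1, 2, 5)]), set())

    def test_geometric_waiting_time(self):
        """B with 20% of inputs from the seed joins per round with p=2/3;
        its distance over many runs is geometric."""
        edges = edge_df([(1, 2, 20), (2, 2, 80)])
        cfg = fl.TraversalConfig(n_runs=10_000, rng_seed=5, max_rounds=200)
        dists = np.array(
            [fl.traversal_run(edges, {1}, cfg, run_index=i)[2] for i in range(2000)]
        )
        p = 2 / 3
        mean, var = 1 / p, (1 - p) / p**2
        assert abs(dists.mean() - mean) < 3 * np.sqrt(var / len(dists))
        # distribution check on the first three rounds
        for k in (1, 2, 3):
            pk = (1 - p) ** (k - 1) * p
            se = np.sqrt(pk * (1 - pk) / len(dists))
            assert abs((dists == k).mean() - pk) < 4 * se


class TestTraversalDistances:
    def test_feedforward_layers_exact(self):
        edges, seeds, depths = generate_layered_network(4, 5, 0.0, rng_seed=0)
        res = fl.traversal_distances(edges, seeds, fl.TraversalConfig(n_runs=10, rng_seed=0))
        got = res.table.set_index("neuron")["mean_distance"]
        for node, depth in depths.items():
            assert got[node] == depth

    def test_percentiles_evenly_spaced_for_distinct_means(self):
        edges = edge_df([(1, 2, 10), (2, 3, 10), (3, 4, 10)])
        res = fl.traversal_distances(edges, {1}, fl.TraversalConfig(n_runs=5, rng_seed=0))
        assert res.table["percentile"].tolist() == [0.0, 100 / 3, 200 / 3, 100.0]

    def test_seeds_have_distance_zero_and_lowest_percentile(self):
        edges = edge_df([(1, 2, 2), (2, 2, 8), (2, 3, 10)])
        res = fl.traversal_distances(edges, {1}, fl.TraversalConfig(n_runs=200, rng_seed=1))
        t = res.table.set_index("neuron")
        assert t.loc[1, "mean_distance"] == 0.0
        assert t.loc[1, "percentile"] == 0.0

    def test_matches_exhaustive_markov_chain_expectations(self):
        """Means over 10,000 runs agree with exact state-enumeration within
        3 Monte-Carlo standard errors."""
        graphs = [
            # diamond with diluting autapses
            edge_df([(1, 2, 3), (2, 2, 7), (1, 3, 6), (3, 3, 4), (2, 4, 5), (3, 4, 5)]),
            # 5-cycle with a chord and mixed weights
            edge_df([(1, 2, 2), (2, 2, 4), (2, 3, 9), (3, 4, 3), (4, 4, 3),
                     (4, 5, 6), (5, 1, 5), (1, 4, 2), (5, 5, 6)]),
        ]
        n_runs = 10_000
        for edges in graphs:
            cfg = fl.TraversalConfig(n_runs=n_runs, rng_seed=7, max_rounds=60)
            res = fl.traversal_distances(edges, {1}, cfg)
            nodes, e1, e2 = traversal_expectations(edges, {1}, 0.3, max_rounds=60)
            got = res.table.set_index("neuron").loc[nodes, "mean_distance"].to_numpy()
            se = np.sqrt(np.maximum(e2 - e1**2, 0.0) / n_runs)
            assert np.all(np.abs(got - e1) <= 3 * np.maximum(se, 1e-12))

    def test_deterministic_graphs_match_shortest_path_hops(self):
        """When every input fraction reaches tau the model is breadth-first."""
        import networkx as nx

        graphs = [
            edge_df([(1, 2, 5), (2, 3, 5), (3, 4, 5), (1, 5, 5), (5, 4, 5)]),
            edge_df([(1, 2, 9), (1, 3, 9), (2, 4, 5), (3, 4, 5), (4, 5, 7)]),
        ]
        for edges in graphs:
            g = nx.from_pandas_edgelist(
                edges, "pre_root_id", "post_root_id", create_using=nx.DiGraph
            )
            hops = nx.single_source_shortest_path_length(g, 1)
            res = fl.traversal_distances(edges, {1}, fl.TraversalConfig(n_runs=50, rng_seed=3))
            got = res.table.set_index("neuron")["mean_distance"]
            for node, h in hops.items():
                assert got[node] == h

    def test_mean_distance_invariant_under_relabeling(self):
        edges = edge_df([(1, 2, 3), (2, 2, 7), (2, 3, 10)])
        relabeled = edge_df([(10, 20, 3), (20, 20, 7), (20, 30, 10)])
        cfg = fl.TraversalConfig(n_runs=4000, rng_seed=11, max_rounds=100)
        a = fl.traversal_distances(edges, {1}, cfg).table.set_index("neuron")["mean_distance"]
        b = fl.traversal_distances(relabeled, {10}, cfg).table.set_index("neuron")["mean_distance"]
        assert abs(a[3] - b[30]) < 0.05  # same chain, independent randomness

    def test_unreached_rule_infinity(self):
        edges = edge_df([(1, 2, 10), (3, 4, 10)])  # 3,4 unreachable from 1
        cfg = fl.TraversalConfig(n_runs=5, rng_seed=0, unreached_distance_rule="infinity")
        res = fl.traversal_distances(edges, {1}, cfg)
        t = res.table.set_index("neuron")
        assert np.isinf(t.loc[4, "mean_distance"])

    def test_layer_rounds_half_away_from_zero(self):
        edges = edge_df([(1, 2, 20), (2, 2, 80)])  # E[d_B] = 1.5 at p = 2/3
        cfg = fl.TraversalConfig(n_runs=20_000, rng_seed=13, max_rounds=100)
        res = fl.traversal_distances(edges, {1}, cfg)
        t = res.table.set_index("neuron")
        assert t.loc[2, "layer"] in (1.0, 2.0)
        assert t.loc[2, "layer"] == np.floor(t.loc[2, "mean_distance"] + 0.5)


class TestRankEmbedding:
    def test_single_modality_equals_result_ranks(self):
        edges = edge_df([(1, 2, 10), (2, 3, 10)])
        emb = fl.build_rank_embedding(edges, {"m": {1}}, fl.TraversalConfig(n_runs=5))
        expected = emb.results["m"].table.set_index("neuron")["rank"]
        pd.testing.assert_series_equal(emb.ranks["m"], expected, check_names=False)

    def test_duplicated_modality_gives_identical_columns(self):
        edges = edge_df([(1, 2, 2), (2, 2, 8), (2, 3, 10)])
        emb = fl.build_rank_embedding(
            edges, {"a": {1}, "b": {1}}, fl.TraversalConfig(n_runs=50, rng_seed=9)
        )
        assert (emb.ranks["a"] == emb.ranks["b"]).all()

    def test_empty_modality_named_in_error(self):
        edges = edge_df([(1, 2, 10)])
        with pytest.raises(ValueError, match="bad_modality"):
            fl.build_rank_embedding(edges, {"ok": {1}, "bad_modality": set()})

    def test_adjacent_layer_seeds_give_correlated_rankings(self):
        """Seeding from layer 0 or layer 1 must order the common downstream
        neurons the same way: both rankings follow depth."""
        edges, seeds, depths = generate_layered_network(4, 6, 0.0, rng_seed=1)
        layer1 = {n for n, d in depths.items() if d == 1}
        emb = fl.build_rank_embedding(
            edges, {"L0": seeds, "L1": layer1},
            fl.TraversalConfig(n_runs=300, rng_seed=2, max_rounds=50),
        )
        downstream = [n for n, d in depths.items() if d >= 2]
        sub = emb.ranks.loc[downstream]
        rho = spearmanr(sub["L0"], sub["L1"]).statistic
        assert rho >= 0.9

    def test_all_modalities_share_one_neuron_universe(self):
        edges, seeds, depths = generate_layered_network(3, 4, 0.0, rng_seed=5)
        emb = fl.build_rank_embedding(
            edges, {"L0": seeds, "one": {next(iter(seeds))}},
            fl.TraversalConfig(n_runs=20, rng_seed=0),
        )
        assert not emb.ranks.isna().any().any()
        assert set(emb.ranks.index) >= seeds


class TestUmap:
    def test_too_few_neurons_suggests_reducing_neighbors(self):
        ranks = pd.DataFrame(np.arange(20).reshape(10, 2), columns=["a", "b"])
        emb = fl.RankEmbedding(ranks=ranks)
        with pytest.raises(ValueError, match="n_neighbors"):
            fl.umap_project(emb)

    def test_planted_clusters_separate_in_two_dimensions(self):
        """Two well-separated blocks in rank space stay separable after
        projection (nearest-centroid accuracy >= 95%)."""
        rng = np.random.default_rng(0)
        n = 60
        block = np.vstack(
            [rng.normal(0, 1, size=(n, 4)), rng.normal(25, 1, size=(n, 4))]
        )
        labels = np.repeat([0, 1], n)
        emb = fl.RankEmbedding(ranks=pd.DataFrame(block, columns=list("abcd")))
        coords = fl.umap_project(emb, rng_seed=0, n_neighbors=15, n_epochs=200).to_numpy()
        c0, c1 = coords[labels == 0].mean(0), coords[labels == 1].mean(0)
        pred = (
            np.linalg.norm(coords - c1, axis=1) < np.linalg.norm(coords - c0, axis=1)
        ).astype(int)
        assert (pred == labels).mean() >= 0.95

    def test_row_count_preserved(self):
        rng = np.random.default_rng(1)
        ranks = pd.DataFrame(rng.random((60, 3)), columns=list("abc"))
        emb = fl.RankEmbedding(ranks=ranks)
        coords = fl.umap_project(emb, rng_seed=0, n_neighbors=10, n_epochs=100)
        assert len(coords) == 60
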