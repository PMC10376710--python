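import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spacetrend import network, preprocess, synthetic


@pytest.fixture(scope="module")
def two_block():
    config = synthetic.two_block_config(
        n_subjects=12, n_measurements=8, amplitude=5, noise_sd=0, seed=4
    )
    records, truth = synthetic.generate_cohort(config)
    prep = preprocess.preprocess_cohort(records)
    pgrams = network.cohort_periodograms(prep.normalized)
    dists, roster = network.periodogram_distances(pgrams)
    return truth, prep, pgrams, dists, roster


class TestDistances:
    def test_identical_series_zero_distance(self, two_block):
        truth, _, _, dists, roster = two_block
        d = dists["M003"]
        block0 = [s for s in roster if truth.blocks[s] == 0]
        assert d.loc[block0[0], block0[1]] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self, two_block):
        _, _, pgrams, dists, _ = two_block
        chunk = pgrams.xs("M001", level="measurement_id")
        d = dists["M001"]
        for a in chunk.index[:4]:
            for b in chunk.index[:4]:
                direct = np.sqrt(np.sum(
                    (chunk.loc[a].to_numpy() - chunk.loc[b].to_numpy()) ** 2
                ))
                assert d.loc[a, b] == pytest.approx(direct, abs=1e-10)

    def test_symmetry_and_zero_diagonal(self, two_block):
        _, _, _, dists, _ = two_block
        for d in dists.values():
            values = d.to_numpy(dtype=float)
            assert np.allclose(values, values.T, equal_nan=True)
            assert np.all(np.diag(values) == 0.0)

    def test_missing_measurement_undefined(self):
        pgrams = pd.DataFrame(
            [[1.0, 2.0], [1.5, 2.5]],
            index=pd.MultiIndex.from_tuples(
                [("S1", "M1"), ("S2", "M2")],
                names=["subject_id", "measurement_id"],
            ),
        )
        dists, roster = network.periodogram_distances(pgrams)
        assert roster == ["S1", "S2"]
        assert np.isnan(dists["M1"].loc["S1", "S2"])


class TestRadius:
    def test_determinism_and_level_monotonicity(self, rng):
        pool = rng.normal(scale=0.3, size=400)
        kw = dict(n_signals=800, n_pairs=20000)
        a = network.similarity_radius(pool, seed=3, **kw)
        b = network.similarity_radius(pool, seed=3, **kw)
        assert a.d_q == b.d_q
        median = network.similarity_radius(pool, level=0.5, seed=3, **kw)
        assert a.d_q >= median.d_q

    def test_calibration_quick(self, rng):
        """~99% of fresh null distances fall strictly below d_q."""
        pool = rng.normal(scale=0.3, size=2000)
        radius = network.similarity_radius(pool, n_signals=4000, n_pairs=200000, seed=5)
        fresh = network.bootstrap_periodogram_distances(
            pool, n_signals=4000, n_pairs=50000, seed=6
        )
        assert np.mean(fresh < radius.d_q) == pytest.approx(0.99, abs=0.01)


class TestAdjacency:
    def test_strict_threshold(self):
        d = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        adj, _, _ = network.restricted_adjacency({"m": d}, 1.0)
        assert adj.loc["a", "b"] == 1
        d.loc["a", "b"] = d.loc["b", "a"] = 1.0   # exactly d_q -> excluded
        adj, _, _ = network.restricted_adjacency({"m": d}, 1.0)
        assert adj.loc["a", "b"] == 0

    def test_edge_weight_counts_similar_measurements(self):
        def mat(v):
            return pd.DataFrame([[0.0, v], [v, 0.0]], index=["a", "b"], columns=["a", "b"])
        dists = {"m1": mat(0.1), "m2": mat(0.2), "m3": mat(5.0)}
        adj, g, edge_meas = network.restricted_adjacency(dists, 1.0)
        assert adj.loc["a", "b"] == 2
        assert g.edges[("a", "b")]["weight"] == 2
        assert edge_meas[("a", "b")] == ["m1", "m2"]

    def test_subject_without_shared_measurements_isolated(self):
        d = pd.DataFrame(
            [[0.0, 0.1, np.nan], [0.1, 0.0, np.nan], [np.nan, np.nan, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        adj, g, _ = network.restricted_adjacency({"m": d}, 1.0)
        assert "c" in g.nodes and g.degree["c"] == 0
        assert adj.loc["c"].sum() == 0

    def test_weights_bounded_by_measurement_count(self, two_block):
        _, _, _, dists, roster = two_block
        adj, _, _ = network.restricted_adjacency(dists, 1e9, roster)
        assert adj.to_numpy().max() <= len(dists)
        values = adj.to_numpy()
        assert np.array_equal(values, values.T)
        assert np.all(np.diag(values) == 0)


class TestConsensus:
    def _cliques(self, n_each=5):
        g = nx.Graph()
        nodes_a = [f"a{i}" for i in range(n_each)]
        nodes_b = [f"b{i}" for i in range(n_each)]
        for group in (nodes_a, nodes_b):
            for i, u in enumerate(group):
                for v in group[i + 1:]:
                    g.add_edge(u, v, weight=3)
        adj = nx.to_pandas_adjacency(g, nodelist=nodes_a + nodes_b, dtype=int)
        return adj, nodes_a, nodes_b

    def test_two_cliques_recovered(self):
        adj, nodes_a, nodes_b = self._cliques()
        labeling = network.consensus_communities(adj, n_runs=50, seed=1)
        truth = [0] * len(nodes_a) + [1] * len(nodes_b)
        assert adjusted_rand_score(truth, labeling.labels.to_numpy()) == 1.0
        assert labeling.k == 2
        np.testing.assert_allclose(labeling.frequencies.sum(axis=1), 1.0)

    def test_node_permutation_invariance(self):
        adj, *_ = self._cliques()
        base = network.consensus_communities(adj, n_runs=30, seed=2)
        perm = list(np.random.default_rng(0).permutation(adj.index))
        permuted = network.consensus_communities(
            adj.loc[perm, perm], n_runs=30, seed=2
        )
        assert adjusted_rand_score(
            base.labels.loc[perm].to_numpy(), permuted.labels.to_numpy()
        ) == 1.0

    def test_fixed_k_bound_and_determinism(self):
        adj, *_ = self._cliques(6)
        labeling = network.consensus_communities(
            adj, k_mode="fixed", k=5, n_runs=30, seed=3
        )
        assert labeling.labels.nunique() <= 5
        again = network.consensus_communities(
            adj, k_mode="fixed", k=5, n_runs=30, seed=3
        )
        pd.testing.assert_series_equal(labeling.labels, again.labels)

    def test_k_larger_than_nodes_rejected(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            network.consensus_communities(adj, k_mode="fixed", k=5, n_runs=5, seed=0)
        with pytest.raises(ValueError, match="2 nodes"):
            network.consensus_communities(adj.iloc[:1, :1], n_runs=5, seed=0)


def test_two_block_cohort_recovery(two_block):
    """Noise-free two-block cohorts are recovered exactly at a strict radius."""
    truth, prep, _, dists, roster = two_block
    pool = prep.normalized.to_numpy(dtype=float).ravel()
    radius = network.similarity_radius(
        pool, n_signals=4000, n_pairs=100000, level=0.25, seed=9
    )
    adj, _, _ = network.restricted_adjacency(dists, radius, roster)
    labeling = network.consensus_communities(adj, n_runs=50, seed=7)
    truth_labels = [truth.blocks[s] for s in roster]
    assert adjusted_rand_score(truth_labels, labeling.labels.to_numpy()) == 1.0


def test_graph_exports(tmp_path, two_block):
    _, _, _, dists, roster = two_block
    adj, g, _ = network.restricted_adjacency(dists, 0.2, roster)
    labeling = network.consensus_communities(adj, n_runs=20, seed=1)
    network.write_graphml(g, labeling, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert back.number_of_nodes() == len(roster)
    assert all("community" in back.nodes[n] for n in back.nodes)
    network.write_edgelist(g, tmp_path / "edges.tsv")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert len(edges) == g.number_of_edges()
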