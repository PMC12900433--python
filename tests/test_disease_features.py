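import networkx as nx
import numpy as np
import pytest

from ddapre.disease_features import (
    WalkConfig,
    build_mesh_dag,
    embed_diseases,
    random_walks,
    train_deepwalk,
)
from ddapre.io_formats import DiseaseRecord, ValidationError


def _cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestBuildMeshDag:
    def test_single_code_chain(self):
        mesh = build_mesh_dag([DiseaseRecord("X", ("A.B.C",))])
        # ancestors A and A.B materialized; leaf node is the disease
        assert set(mesh.graph.nodes) == {"A", "A.B", "X"}
        assert set(mesh.graph.edges) == {("A", "A.B"), ("A.B", "X")}
        assert mesh.code_to_node["A.B.C"] == "X"

    def test_multi_code_disease_reachable_from_both_roots(self):
        mesh = build_mesh_dag([DiseaseRecord("X", ("A.B", "X1.Y"))])
        assert nx.has_path(mesh.graph, "A", "X")
        assert nx.has_path(mesh.graph, "X1", "X")

    def test_shared_prefix_common_ancestor_out_degree(self):
        mesh = build_mesh_dag(
            [
                DiseaseRecord("X", ("A.B.C",)),
                DiseaseRecord("Y", ("A.B.D",)),
            ]
        )
        assert mesh.graph.out_degree("A.B") >= 2

    def test_acyclic_on_fixture(self, toy_diseases):
        mesh = build_mesh_dag(toy_diseases)
        assert nx.is_directed_acyclic_graph(mesh.graph)

    def test_ancestor_closure(self, toy_diseases):
        mesh = build_mesh_dag(toy_diseases)
        for node, data in mesh.graph.nodes(data=True):
            for code in data["codes"]:
                if "." in code:
                    parent = code.rsplit(".", 1)[0]
                    assert parent in mesh.code_to_node

    def test_malformed_code_named_in_error(self):
        # bypass the record's own validation to exercise the DAG builder's
        record = DiseaseRecord("X", ("A.B",))
        object.__setattr__(record, "tree_numbers", ("A..B",))
        with pytest.raises(ValidationError, match="malformed"):
            build_mesh_dag([record])

    def test_code_claimed_twice_rejected(self):
        with pytest.raises(ValidationError, match="claimed"):
            build_mesh_dag(
                [DiseaseRecord("X", ("A.B",)), DiseaseRecord("Y", ("A.B",))]
            )


class TestRandomWalks:
    def test_walks_follow_edges(self, toy_diseases):
        mesh = build_mesh_dag(toy_diseases)
        cfg = WalkConfig(walks_per_node=2, walk_length=10, seed=0)
        undirected = mesh.graph.to_undirected()
        walks = random_walks(mesh, cfg)
        assert len(walks) == 2 * mesh.graph.number_of_nodes()
        for walk in walks:
            for a, b in zip(walk, walk[1:]):
                assert undirected.has_edge(a, b)

    def test_uniform_transition_frequency(self):
        # node with exactly two neighbors: each visited ~50% of steps out
        mesh = build_mesh_dag([DiseaseRecord("X", ("A.B",)), DiseaseRecord("Y", ("A.C",))])
        # A's neighbors are X (A.B) and Y (A.C)
        cfg = WalkConfig(walks_per_node=400, walk_length=30, seed=3)
        walks = random_walks(mesh, cfg)
        follows = [
            walk[i + 1]
            for walk in walks
            for i in range(len(walk) - 1)
            if walk[i] == "A"
        ]
        count_x = sum(1 for f in follows if f == "X")
        n = len(follows)
        assert n > 10000
        sigma = np.sqrt(0.25 / n)
        assert abs(count_x / n - 0.5) < 3 * sigma

    def test_isolated_node_walk_length_one(self):
        mesh = build_mesh_dag([DiseaseRecord("X", ("A",))])
        walks = random_walks(mesh, WalkConfig(walks_per_node=2, seed=0))
        assert all(walk == ["X"] for walk in walks)

    def test_deterministic_under_seed(self, toy_diseases):
        mesh = build_mesh_dag(toy_diseases)
        cfg = WalkConfig(walks_per_node=2, walk_length=8, seed=9)
        assert random_walks(mesh, cfg) == random_walks(mesh, cfg)


class TestTrainDeepwalk:
    def test_default_dimension_64(self):
        mesh = build_mesh_dag([DiseaseRecord("X", ("A.B",)), DiseaseRecord("Y", ("A.C",))])
        cfg = WalkConfig(walks_per_node=2, walk_length=5, epochs=1, seed=0)
        model = train_deepwalk(random_walks(mesh, cfg), cfg)
        assert all(len(model[v]) == 64 for v in model.vocab)

    def test_disconnected_cliques_separate(self):
        sentences_graph = nx.disjoint_union(
            nx.complete_graph(5), nx.complete_graph(5)
        )
        # walks directly over this toy graph via an adapter mesh
        from ddapre.disease_features import MeshGraph

        digraph = nx.DiGraph()
        for u, v in sentences_graph.edges:
            digraph.add_edge(str(u), str(v))
        mesh = MeshGraph(digraph)
        wins = 0
        for seed in range(20):
            cfg = WalkConfig(
                walks_per_node=8, walk_length=12, window=4,
                dimension=16, epochs=3, seed=seed,
            )
            model = train_deepwalk(random_walks(mesh, cfg), cfg)
            a = [model[str(i)] for i in range(5)]
            b = [model[str(i)] for i in range(5, 10)]
            within = np.mean(
                [_cosine(u, v) for i, u in enumerate(a) for j, v in enumerate(a) if i < j]
                + [_cosine(u, v) for i, u in enumerate(b) for j, v in enumerate(b) if i < j]
            )
            cross = np.mean([_cosine(u, v) for u in a for v in b])
            wins += within > cross
        assert wins > 10

    def test_parent_child_closer_than_random(self, toy_diseases):
        mesh = build_mesh_dag(toy_diseases)
        edges = list(mesh.graph.edges)
        nodes = sorted(mesh.graph.nodes)
        wins = 0
        for seed in range(20):
            cfg = WalkConfig(
                walks_per_node=6, walk_length=15, window=4,
                dimension=16, epochs=3, seed=seed,
            )
            model = train_deepwalk(random_walks(mesh, cfg), cfg)
            edge_sim = np.mean([_cosine(model[a], model[b]) for a, b in edges])
            rng = np.random.default_rng(seed)
            pairs = rng.choice(len(nodes), size=(200, 2))
            rand_sim = np.mean(
                [
                    _cosine(model[nodes[i]], model[nodes[j]])
                    for i, j in pairs
                    if i != j
                ]
            )
            wins += edge_sim > rand_sim
        assert wins > 10

    def test_empty_walks_rejected(self):
        with pytest.raises(ValueError):
            train_deepwalk([], WalkConfig())


class TestEmbedDiseases:
    def test_every_disease_embedded_at_dimension(self, toy_diseases):
        cfg = WalkConfig(
            walks_per_node=3, walk_length=10, dimension=16, epochs=2, seed=1
        )
        table = embed_diseases(toy_diseases, cfg)
        assert len(table) == len(toy_diseases)
        assert table.dimension == 16
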