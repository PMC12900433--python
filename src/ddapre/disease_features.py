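"""MeSH TreeNumber DAG construction and DeepWalk disease embedding.

Each disease contributes its TreeNumber codes; progressively truncating
the trailing dotted segment of every code materializes all ancestor
concepts, giving a rooted DAG. A catalogue disease is a single node
carrying all of its codes (so a disease filed under several branches is
reachable from several roots); ancestor concepts not in the catalogue
are nodes keyed by their code. Uniform truncated random walks over the
undirected neighborhood of the DAG feed a skip-gram model, so
hierarchically related diseases land close in the embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ddapre.io_formats import DiseaseRecord, EmbeddingTable, ValidationError
from ddapre.skipgram import train_skipgram

DEFAULT_DIMENSION = 64


@dataclass
class MeshGraph:
    """Disease concept DAG addressable both by node id and by tree code."""

    graph: nx.DiGraph
    code_to_node: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class WalkConfig:
    """Random-walk / skip-gram settings for DeepWalk."""

    walks_per_node: int = 10
    walk_length: int = 40
    window: int = 5
    dimension: int = DEFAULT_DIMENSION
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")


def _parent_code(code: str) -> str | None:
    head, _, _ = code.rpartition(".")
    return head or None


def build_mesh_dag(diseases: list[DiseaseRecord]) -> MeshGraph:
    """Build the ancestor DAG by tail-truncation of TreeNumber codes.

    Node ids are disease ids for catalogue diseases (one node per
    disease, however many codes it owns) and raw codes for materialized
    ancestors. Edges run parent -> child by single-segment truncation.
    Acyclic by construction: every edge goes from a strictly shorter
    code to a longer one. A code claimed by two diseases is rejected.
    """
    code_owner: dict[str, str] = {}
    for record in diseases:
        for code in record.tree_numbers:
            if any(not seg for seg in code.split(".")):
                raise ValidationError(f"malformed tree number {code!r}")
            prior = code_owner.get(code)
            if prior is not None and prior != record.disease_id:
                raise ValidationError(
                    f"tree number {code!r} claimed by both {prior!r} "
                    f"and {record.disease_id!r}"
                )
            code_owner[code] = record.disease_id

    def node_of(code: str) -> str:
        return code_owner.get(code, code)

    graph = nx.DiGraph()
    code_to_node: dict[str, str] = {}
    all_codes: set[str] = set()
    for record in diseases:
        for code in record.tree_numbers:
            chain = []
            cursor: str | None = code
            while cursor is not None:
                chain.append(cursor)
                cursor = _parent_code(cursor)
            all_codes.update(chain)
    for code in sorted(all_codes):
        node = node_of(code)
        code_to_node[code] = node
        if node not in graph:
            graph.add_node(node, codes=set(), in_catalogue=node in code_owner.values())
        graph.nodes[node]["codes"].add(code)
    for code in sorted(all_codes):
        parent = _parent_code(code)
        if parent is not None:
            u, v = node_of(parent), node_of(code)
            if u != v:
                graph.add_edge(u, v)
    return MeshGraph(graph, code_to_node)


def random_walks(mesh: MeshGraph, cfg: WalkConfig) -> list[list[str]]:
    """Uniform truncated random walks, ``walks_per_node`` per start node.

    Walks traverse the undirected neighborhood (parents and children), so
    leaf concepts do not trap the walker; an isolated node yields a
    length-1 walk. The next node is uniformly sampled among neighbors.
    """
    graph = mesh.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    undirected = graph.to_undirected(as_view=True)
    nodes = sorted(graph.nodes)
    neighbors = {v: sorted(undirected.neighbors(v)) for v in nodes}
    walks = []
    for _ in range(cfg.walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < cfg.walk_length:
                nbrs = neighbors[walk[-1]]
                if not nbrs:
                    break
                walk.append(nbrs[rng.integers(len(nbrs))])
            walks.append(walk)
    return walks


def train_deepwalk(walks: list[list[str]], cfg: WalkConfig):
    """Skip-gram over walk sequences; returns the node->vector model."""
    if not walks:
        raise ValueError("empty walk set")
    return train_skipgram(
        walks,
        dimension=cfg.dimension,
        window=cfg.window,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )


def embed_diseases(
    diseases: list[DiseaseRecord],
    cfg: WalkConfig | None = None,
    include_ancestors: bool = False,
) -> EmbeddingTable:
    """End-to-end disease embedding: DAG -> walks -> skip-gram -> table.

    Each catalogue disease is one walk-graph node, so its embedding is a
    direct lookup. Ancestor concepts absent from the catalogue get
    embeddings too but are only emitted (keyed ``code:<tree number>``)
    under ``include_ancestors``.
    """
    cfg = cfg or WalkConfig()
    mesh = build_mesh_dag(diseases)
    model = train_deepwalk(random_walks(mesh, cfg), cfg)
    table: dict[str, np.ndarray] = {}
    for record in diseases:
        if record.disease_id not in model:
            raise ValueError(f"disease {record.disease_id!r} not embedded")
        table[record.disease_id] = model[record.disease_id]
    if include_ancestors:
        catalogue = {r.disease_id for r in diseases}
        for node, data in mesh.graph.nodes(data=True):
            if node not in catalogue and node in model:
                for code in data["codes"]:
                    table[f"code:{code}"] = model[node]
    return EmbeddingTable(table, dimension=cfg.dimension)
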