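"""Seed-anchored expansion of an interaction database into a working graph.

The seed genes are mapped onto the database graph and grown outward by a
configurable number of hops (default 1, first neighbors); the result is the
induced subgraph on every node reached, so neighbor-neighbor edges are kept.
Interaction direction and type are ignored: the graph is simple, undirected
and unweighted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from subnetmark.diffexpr import SeedGeneSet

logger = logging.getLogger(__name__)


@dataclass
class InteractionGraph:
    """Simple undirected graph over gene symbols with per-node seed flags."""

    graph: nx.Graph
    seeds: set[str]

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        missing = self.seeds - set(self.graph.nodes)
        if missing:
            raise ValueError(f"seed nodes outside graph: {sorted(missing)[:5]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def is_seed(self, node: str) -> bool:
        return node in self.seeds


def expand_network(
    seeds: SeedGeneSet | Iterable[str],
    db_edges: Iterable[tuple[str, str]],
    hops: int = 1,
) -> InteractionGraph:
    """Grow the network `hops` steps from the seeds and induce all edges.

    Node set = seeds plus every database node within ``hops`` edges of a
    seed; edge set = all database edges with both endpoints inside that node
    set. Seeds absent from the database are kept as isolated flagged nodes
    (warning); if no seed maps at all, that is an error.
    """
    if hops < 0:
        raise ValueError("hops must be >= 0")
    seed_set = set(seeds.symbols if isinstance(seeds, SeedGeneSet) else seeds)
    if not seed_set:
        raise ValueError("empty seed set")

    db = nx.Graph()
    for a, b in db_edges:
        if a != b:
            db.add_edge(a, b)

    mapped = seed_set & set(db.nodes)
    if not mapped:
        raise ValueError("no seed mapped to the interaction database")
    unmapped = seed_set - mapped
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} seed genes absent from the interaction database; "
            "retained as isolated nodes"
        )

    frontier = set(mapped)
    reached = set(mapped)
    for _ in range(hops):
        nxt = set()
        for node in frontier:
            nxt.update(db.neighbors(node))
        frontier = nxt - reached
        reached |= nxt
        if not frontier:
            break

    g = db.subgraph(reached).copy()
    g.add_nodes_from(seed_set)  # isolated unmapped seeds
    logger.info(
        "expanded network: %d nodes, %d edges from %d seeds (%d mapped)",
        g.number_of_nodes(), g.number_of_edges(), len(seed_set), len(mapped),
    )
    return InteractionGraph(g, seed_set)


def graph_stats(g: InteractionGraph) -> dict:
    """Node/edge/seed/component counts, degree distribution, and a hub report."""
    graph = g.graph
    degrees = dict(graph.degree())
    hubs = sorted(degrees, key=lambda n: (-degrees[n], n))
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_seeds": len(g.seeds & set(graph.nodes)),
        "n_components": nx.number_connected_components(graph) if graph else 0,
        "degree_distribution": {n: degrees[n] for n in sorted(degrees)},
        "hubs": hubs[:20],
    }
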