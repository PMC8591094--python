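"""Markov Cluster Algorithm (MCL) and the subnetwork selection rule.

MCL clusters a graph by simulating flow: the column-stochastic transition
matrix is alternately *expanded* (matrix power, letting flow spread) and
*inflated* (entry-wise power followed by column renormalization, boosting
strong currents and starving weak ones) until the flow stabilizes into
disjoint attractor regions, which are read off as clusters. Larger inflation
yields more, smaller clusters.

The implementation is dense numpy with entry pruning; the graphs this
package clusters are desk scale (up to a few thousand nodes), where dense
linear algebra is simpler and fast enough.

Clusters that contain at least one seed gene and at least ``min_nodes``
members (default 3) become subnetwork markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from subnetmark.diffexpr import SeedGeneSet
from subnetmark.network import InteractionGraph

logger = logging.getLogger(__name__)


@dataclass
class MCLParams:
    """Tunables for the flow simulation.

    expansion_e : int >= 2
        Matrix power of the expansion step.
    inflation_r : float > 1
        Entry-wise exponent; the granularity knob.
    self_loop_weight : float >= 0
        Added to the diagonal before normalization; damps parity effects.
    prune_threshold : float >= 0
        Entries below this are zeroed (then columns renormalized).
    max_iterations, convergence_tol
        Iteration is stopped when the max absolute entry change falls below
        the tolerance, or at the iteration cap with a warning flag.
    """

    expansion_e: int = 2
    inflation_r: float = 2.0
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.expansion_e < 2:
            raise ValueError("expansion_e must be >= 2")
        if self.inflation_r <= 1:
            raise ValueError("inflation_r must be > 1")
        if self.self_loop_weight < 0 or self.prune_threshold < 0:
            raise ValueError("weights/thresholds must be non-negative")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class MCLResult:
    """Clustering outcome plus per-iteration diagnostics.

    ``clusters`` is a partition: every node appears in exactly one cluster.
    ``column_sum_errors`` records, per iteration, the maximum deviation of
    any column sum from 1 measured right after the inflate/renormalize step;
    ``changes`` the max absolute entry change per iteration.
    """

    clusters: list[set[str]]
    converged: bool
    n_iterations: int
    column_sum_errors: list[float] = field(default_factory=list)
    changes: list[float] = field(default_factory=list)
    matrix: np.ndarray | None = None
    node_order: list[str] = field(default_factory=list)


@dataclass
class Subnetwork:
    """A filtered MCL cluster used as a single marker feature.

    ``up_set``/``down_set`` (disjoint subsets of members) are filled later by
    the scoring module from training-data expression directions.
    """

    id: int
    members: set[str]
    seed_members: set[str]
    up_set: set[str] = field(default_factory=set)
    down_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.seed_members <= self.members:
            raise ValueError("seed_members must be a subset of members")
        if self.up_set & self.down_set:
            raise ValueError("up_set and down_set must be disjoint")

    def __len__(self) -> int:
        return len(self.members)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    """Column-stochastic rescale; a dead column gets unit mass on its diagonal."""
    sums = m.sum(axis=0)
    dead = sums == 0
    if dead.any():
        m[np.where(dead)[0], np.where(dead)[0]] = 1.0
        sums = m.sum(axis=0)
    return m / sums


def mcl_cluster(g: InteractionGraph, params: MCLParams | None = None) -> MCLResult:
    """Run MCL on the graph and extract a hard partition.

    The adjacency matrix (plus self-loop weight on the diagonal) is
    column-normalized, then expand / inflate+renormalize / prune+renormalize
    steps repeat until the matrix stops changing. Clusters are the connected
    components of the nonzero off-diagonal structure of the converged matrix
    (symmetrized). Should any interpretation yield overlapping attractor
    sets, a node is assigned to the largest cluster, ties broken toward the
    cluster containing the lexicographically smallest member; component
    extraction already produces disjoint clusters, so this is a safety net.

    Non-convergence at ``max_iterations`` is reported via the result's
    ``converged`` flag and a warning, never an exception.
    """
    params = params or MCLParams()
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    a = np.zeros((n, n))
    for e in g.edges:
        pair = tuple(e)
        i, j = index[pair[0]], index[pair[1]]
        a[i, j] = a[j, i] = 1.0
    np.fill_diagonal(a, params.self_loop_weight)

    m = _normalize_columns(a)
    column_sum_errors: list[float] = []
    changes: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        previous = m
        m = np.linalg.matrix_power(m, params.expansion_e)
        m = _normalize_columns(m**params.inflation_r)
        column_sum_errors.append(float(np.abs(m.sum(axis=0) - 1.0).max()))
        if params.prune_threshold > 0:
            m = np.where(m < params.prune_threshold, 0.0, m)
            m = _normalize_columns(m)
        change = float(np.abs(m - previous).max())
        changes.append(change)
        if change < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations "
            f"(last change {changes[-1]:.2e}); returning current clustering"
        )

    clusters = _extract_clusters(m, nodes)
    logger.info(
        "MCL: %d nodes -> %d clusters in %d iterations (converged=%s)",
        n, len(clusters), iteration, converged,
    )
    return MCLResult(
        clusters=clusters,
        converged=converged,
        n_iterations=iteration,
        column_sum_errors=column_sum_errors,
        changes=changes,
        matrix=m,
        node_order=nodes,
    )


def _extract_clusters(m: np.ndarray, nodes: list[str]) -> list[set[str]]:
    support = (m > 0) | (m > 0).T
    np.fill_diagonal(support, True)
    n_comp, labels = connected_components(csr_matrix(support), directed=False)
    raw: list[set[str]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        raw[lab].add(node)
    clusters = _resolve_overlaps(raw)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


def _resolve_overlaps(raw: list[set[str]]) -> list[set[str]]:
    """Assign multiply-attracted nodes to the largest cluster (tie: the one
    holding the lexicographically smallest member); a no-op for disjoint input."""
    owner: dict[str, int] = {}
    for ci, cluster in enumerate(raw):
        for node in cluster:
            if node not in owner:
                owner[node] = ci
            else:
                current = raw[owner[node]]
                challenger = cluster
                if (len(challenger), min(current)) > (len(current), min(challenger)):
                    owner[node] = ci
    resolved: dict[int, set[str]] = {}
    for node, ci in owner.items():
        resolved.setdefault(ci, set()).add(node)
    return [c for c in resolved.values() if c]


def filter_subnetworks(
    clusters: list[set[str]],
    seeds: SeedGeneSet | set[str],
    min_nodes: int = 3,
) -> list[Subnetwork]:
    """Keep clusters with >=1 seed member and >= min_nodes members.

    Survivors are ordered by size descending, then by lexicographically
    smallest member, and assigned ids 1..n in that order.
    """
    seed_set = set(seeds.symbols if isinstance(seeds, SeedGeneSet) else seeds)
    kept = [
        c for c in clusters if len(c) >= min_nodes and c & seed_set
    ]
    if not kept:
        raise ValueError("no subnetwork markers: every cluster is too small or seedless")
    kept.sort(key=lambda c: (-len(c), min(c)))
    return [
        Subnetwork(id=i, members=c, seed_members=c & seed_set)
        for i, c in enumerate(kept, start=1)
    ]
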