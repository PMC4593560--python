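"""Interaction-network loading, hub pruning and centrality measures.

Degree, betweenness and the participation coefficient are the three
network-role measures compared between multifunctional and other genes.
Betweenness is the standard unweighted shortest-path centrality (paths
between a pair weighted inversely to the number of distinct shortest
paths, endpoints excluded), reported unnormalized since only rank
comparisons between gene groups consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

import networkx as nx
import networkx.algorithms.community as nx_comm

logger = logging.getLogger(__name__)

DEFAULT_MAX_DEGREE = 200


@dataclass
class InteractionNetwork:
    """A simple undirected graph over genes (no self-loops, no multi-edges)."""

    graph: nx.Graph
    bait_prey: set[tuple[str, str]] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_edges(stream: IO[str], directed_bait_prey: bool = False) -> InteractionNetwork:
    """Read a two-column TSV edge list into a simple graph.

    Duplicate edges are collapsed and self-loops dropped (with a logged
    count).  When ``directed_bait_prey`` is set, the original bait->prey
    orientation of each line is kept in metadata for bait-degree analyses.
    """
    g = nx.Graph()
    bait_prey: set[tuple[str, str]] = set()
    n_loops = 0
    n_edges_seen = 0
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            logger.warning("line %d: malformed edge row %r, skipped", lineno, line)
            continue
        a, b = parts[0], parts[1]
        if a == b:
            n_loops += 1
            continue
        n_edges_seen += 1
        g.add_edge(a, b)
        if directed_bait_prey:
            bait_prey.add((a, b))
    if g.number_of_edges() == 0:
        raise ValueError("edge list contains no valid edges")
    if n_loops:
        logger.info("dropped %d self-loops", n_loops)
    return InteractionNetwork(graph=g, bait_prey=bait_prey)


def remove_hubs(net: InteractionNetwork, max_degree: int = DEFAULT_MAX_DEGREE) -> InteractionNetwork:
    """Iteratively remove likely-artifactual super-connectors.

    In each iteration the single node of highest degree exceeding
    ``max_degree`` is removed along with its edges (ties broken
    lexicographically by id) and degrees are recomputed; the result has
    maximum degree <= ``max_degree``.  Idempotent.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    g = net.graph.copy()
    while True:
        over = [(d, n) for n, d in g.degree if d > max_degree]
        if not over:
            break
        max_d = max(d for d, _ in over)
        worst = min(n for d, n in over if d == max_d)  # lexicographic tie-break
        g.remove_node(worst)
    return InteractionNetwork(graph=g, bait_prey=set(net.bait_prey))


def degree(net: InteractionNetwork) -> dict[str, int]:
    return dict(net.graph.degree)


def betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (endpoints excluded)."""
    return nx.betweenness_centrality(net.graph, normalized=False)


def participation(net: InteractionNetwork, clusters: Mapping[str, object]) -> dict[str, float]:
    """Participation coefficient ``P = 1 - sum_i (k_i / k)^2``.

    ``k`` is the node degree and ``k_i`` the number of its edges into
    cluster ``i``; 0 when all edges stay in one cluster, approaching 1 as
    edges spread uniformly over clusters.  Degree-0 nodes get ``P = 0`` so
    downstream rank statistics stay total.
    """
    missing = set(net.graph.nodes) - set(clusters)
    if missing:
        raise ValueError(f"cluster assignment missing {len(missing)} nodes, e.g. {sorted(missing)[:3]}")
    out: dict[str, float] = {}
    for v in net.graph.nodes:
        k = net.graph.degree(v)
        if k == 0:
            logger.debug("node %s has degree 0; participation defined as 0", v)
            out[v] = 0.0
            continue
        per_cluster: dict[object, int] = {}
        for u in net.graph.neighbors(v):
            c = clusters[u]
            per_cluster[c] = per_cluster.get(c, 0) + 1
        out[v] = 1.0 - sum((ki / k) ** 2 for ki in per_cluster.values())
    return out


def modularity(net: InteractionNetwork, clusters: Mapping[str, object]) -> float:
    """Newman's modularity Q of a partition."""
    groups: dict[object, set[str]] = {}
    for node, c in clusters.items():
        if node in net.graph:
            groups.setdefault(c, set()).add(node)
    return nx_comm.modularity(net.graph, list(groups.values()))


def greedy_cluster(net: InteractionNetwork, seed: int | None = None) -> dict[str, int]:
    """Greedy agglomerative modularity clustering (CNM).

    A deterministic baseline partition whose modularity is at least that of
    the all-singletons partition; production runs can plug in an external
    cluster assignment (e.g. SPICi output) instead.  ``seed`` is accepted
    for interface stability; the algorithm is deterministic.
    """
    communities = nx_comm.greedy_modularity_communities(net.graph)
    assignment: dict[str, int] = {}
    for label, members in enumerate(sorted(communities, key=lambda s: sorted(s)[0])):
        for node in members:
            assignment[node] = label
    return assignment


def load_clusters(stream: IO[str]) -> dict[str, str]:
    """Read a ``gene<TAB>cluster_id`` TSV."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            logger.warning("line %d: malformed cluster row %r, skipped", lineno, line)
            continue
        out[parts[0]] = parts[1]
    if not out:
        raise ValueError("cluster file contains no assignments")
    return out
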