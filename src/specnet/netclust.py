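"""Interaction-graph construction, Markov clustering (MCL), cluster ranking
and betweenness centrality.

The MCL implementation is the literal algorithm: build a column-stochastic
matrix from the weighted adjacency with self-loops, then alternate expansion
(matrix squaring) and inflation (entrywise power followed by column
re-normalization) with pruning of tiny entries, until the matrix stops
changing.  Clusters are read off the attractor structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4
DEFAULT_INFLATION = 1.9


@dataclass
class ClusterSet:
    """Partition of graph nodes; clusters ordered by size rank (1 = largest)."""

    clusters: list[list[str]]                       # sorted member lists
    betweenness: dict[str, float] = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def size_ranks(self) -> list[int]:
        return list(range(1, len(self.clusters) + 1))

    def membership(self) -> dict[str, int]:
        return {n: i for i, members in enumerate(self.clusters) for n in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (node, i + 1, len(members))
            for i, members in enumerate(self.clusters)
            for node in members
        ]
        return pd.DataFrame(rows, columns=["node", "cluster_rank", "cluster_size"])


def build_graph(
    edges: pd.DataFrame,
    node_universe: list[str] | set[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> nx.Graph:
    """Graph over ``node_universe`` keeping edges with score >= threshold.

    Isolated universe nodes are retained.  The threshold is stored on the
    graph as provenance.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    universe = {str(n).upper() for n in node_universe}
    if not universe:
        raise ValueError("empty node universe")
    G = nx.Graph(threshold=threshold)
    G.add_nodes_from(sorted(universe))
    n_kept = 0
    for a, b, score in edges[["node_a", "node_b", "score"]].itertuples(index=False):
        if a in universe and b in universe and score >= threshold and a != b:
            prev = G.get_edge_data(a, b)
            if prev is None or score > prev["weight"]:
                G.add_edge(a, b, weight=float(score))
            n_kept += 1
    if n_kept == 0:
        logger.warning("no edges retained: universe disjoint from edge table or all below threshold")
    return G


def _column_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    dead = sums == 0
    if dead.any():  # column lost all mass to pruning; park it on the diagonal
        for j in np.flatnonzero(dead):
            M[j, j] = 1.0
        sums = M.sum(axis=0)
    return M / sums


def inflate(M: np.ndarray, inflation: float, prune: float) -> np.ndarray:
    """Entrywise power, re-normalize, prune small entries, re-normalize."""
    M = _column_normalize(M ** inflation)
    M[M < prune] = 0.0
    return _column_normalize(M)


def mcl(
    graph: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Self-loop weight is each node's maximum incident edge weight (1 for
    isolated nodes).  Returns a deterministic partition: nodes are assigned
    to their strongest attractor, attractors sharing support are merged.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1 (no contraction otherwise)")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = w
    for i in range(n):
        inc = A[i].max()
        A[i, i] = inc if inc > 0 else 1.0

    M = _column_normalize(A)
    converged = False
    for _ in range(max_iter):
        M_new = inflate(M @ M, inflation, prune)
        if np.max(np.abs(M_new - M)) < tol:
            M = M_new
            converged = True
            break
        M = M_new
    if not converged:
        logger.warning("MCL did not converge within %d iterations; returning partial result", max_iter)

    return ClusterSet(clusters=_interpret(M, nodes))


def _interpret(M: np.ndarray, nodes: list[str]) -> list[list[str]]:
    """Read clusters off the converged matrix.

    Attractors are nodes with positive diagonal mass; attractors whose rows
    share support belong to one attractor system; each node joins the system
    of its strongest attractor (ties to the lexicographically smallest).
    """
    n = len(nodes)
    attractors = [i for i in range(n) if M[i, i] > 0]
    if not attractors:  # numerically possible only pre-convergence
        attractors = list(range(n))
    # union-find over attractors sharing row support
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    support = {a: set(np.flatnonzero(M[a]).tolist()) for a in attractors}
    for i, a in enumerate(attractors):
        for b in attractors[i + 1:]:
            if support[a] & support[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), set()).add(a)

    assignment: dict[int, int] = {}
    for j in range(n):
        best_mass = max(M[a, j] for a in attractors)
        if best_mass == 0:  # column mass fell entirely outside attractors
            candidates = sorted((nodes[a], a) for a in attractors)
        else:
            # strongest attractor; ties to the lexicographically smallest label
            candidates = sorted((nodes[a], a) for a in attractors if M[a, j] == best_mass)
        assignment[j] = find(candidates[0][1])

    clusters_by_root: dict[int, list[str]] = {}
    for j, root in assignment.items():
        clusters_by_root.setdefault(root, []).append(nodes[j])
    clusters = [sorted(members) for members in clusters_by_root.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def rank_clusters(
    cluster_set: ClusterSet,
    graph: nx.Graph,
    top_k: int = 8,
) -> list[list[str]]:
    """Clusters by size descending; ties by total internal edge weight
    descending, then by lexicographically smallest member."""
    def internal_weight(members: list[str]) -> float:
        mset = set(members)
        return sum(
            d["weight"]
            for a, b, d in graph.edges(data=True)
            if a in mset and b in mset
        )

    ordered = sorted(
        cluster_set.clusters,
        key=lambda c: (-len(c), -internal_weight(c), c[0]),
    )
    if len(ordered) < top_k:
        logger.info("only %d clusters available (top_k=%d)", len(ordered), top_k)
    return ordered[:top_k]


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Shortest-path betweenness on the unweighted topology, normalized by
    (n-1)(n-2)/2 within each connected component; nodes in components of
    size < 3 score 0."""
    cent = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        if len(comp) < 3:
            continue
        sub = graph.subgraph(comp)
        cent.update(nx.betweenness_centrality(sub, normalized=True, weight=None))
    return cent
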