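"""MCODE complex detection: vertex weighting, prediction, post-processing.

Vertices are weighted by the core-clustering coefficient (highest k-core
of the closed neighborhood, k times its density).  Complexes grow
breadth-first from the heaviest unvisited seed, including neighbors
whose weight exceeds ``(1 - node_score_cutoff)`` of the seed weight
(strict inequality).  Complexes are scored by density times node count.
"""

from __future__ import annotations

import heapq
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "MCODEParams",
    "MCODEComplex",
    "core_decomposition",
    "vertex_weight",
    "vertex_weights",
    "predict_complexes",
    "haircut",
    "fluff",
    "complex_score",
    "write_complexes_tsv",
]


@dataclass(frozen=True)
class MCODEParams:
    k_core: int = 4
    node_score_cutoff: float = 0.3
    degree_cutoff: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if not 0 <= self.node_score_cutoff < 1:
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.degree_cutoff < 2:
            raise ValueError("degree_cutoff must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 <= self.fluff_density_cutoff <= 1:
            raise ValueError("fluff_density_cutoff must lie in [0, 1]")


@dataclass(frozen=True)
class MCODEComplex:
    members: frozenset
    seed: str
    score: float
    n_nodes: int
    n_edges: int


def core_decomposition(net: nx.Graph) -> dict[str, int]:
    """Core number of every node (largest k with v in a min-degree-k subgraph).

    Min-degree peeling with a lazy heap; O(E log V).
    """
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}  # heap ties break on index
    deg = dict(net.degree())
    core: dict[str, int] = {}
    remaining = set(nodes)
    heap = [(deg[v], i) for i, v in enumerate(nodes)]
    heapq.heapify(heap)
    k = 0
    while heap:
        d, i = heapq.heappop(heap)
        v = nodes[i]
        if v not in remaining or d != deg[v]:
            continue
        k = max(k, d)
        core[v] = k
        remaining.remove(v)
        for u in net[v]:
            if u in remaining:
                deg[u] -= 1
                heapq.heappush(heap, (deg[u], index[u]))
    return core


def _density(net: nx.Graph) -> float:
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def vertex_weight(net: nx.Graph, v) -> float:
    """Core-clustering coefficient of ``v``.

    k times the density of the highest k-core of the subgraph induced by
    the closed neighborhood N[v]; 0 for isolated vertices.  The highest
    core need not contain ``v`` itself.
    """
    closed = set(net[v]) | {v}
    sub = net.subgraph(closed)
    if sub.number_of_edges() == 0:
        return 0.0
    core = core_decomposition(sub)
    k_max = max(core.values())
    top = [u for u, k in core.items() if k >= k_max]
    return k_max * _density(sub.subgraph(top))


def vertex_weights(net: nx.Graph) -> dict[str, float]:
    return {v: vertex_weight(net, v) for v in net}


def complex_score(n_nodes: int, n_edges: int) -> float:
    """Density times node count: ``2 E / (V - 1)``; 0 below two nodes."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes - 1)


def haircut(members: Iterable, net: nx.Graph, seed=None) -> frozenset:
    """Iteratively drop members with <2 within-complex neighbors.

    The trim can disconnect the complex, in which case the component
    containing the seed is kept (largest component, smallest member id,
    when no seed survives).  May return an empty set.
    """
    sub = net.subgraph(set(members)).copy()
    while True:
        low = [v for v, d in sub.degree() if d < 2]
        if not low:
            break
        sub.remove_nodes_from(low)
    if sub.number_of_nodes() == 0:
        return frozenset()
    components = sorted(
        nx.connected_components(sub), key=lambda c: (-len(c), min(map(str, c)))
    )
    if seed is not None:
        for comp in components:
            if seed in comp:
                return frozenset(comp)
    return frozenset(components[0])


def fluff(members: Iterable, net: nx.Graph, density_cutoff: float) -> frozenset:
    """Add boundary neighbors whose closed-neighborhood density exceeds
    the cutoff (strict); complexes may overlap after fluffing."""
    members = set(members)
    added = set()
    for v in sorted(members, key=str):
        for u in net[v]:
            if u in members or u in added:
                continue
            if _density(net.subgraph(set(net[u]) | {u})) > density_cutoff:
                added.add(u)
    return frozenset(members | added)


def predict_complexes(
    net: nx.Graph, params: MCODEParams | None = None
) -> list[MCODEComplex]:
    """Run the full MCODE prediction on a simple undirected graph.

    Seeds are processed in descending weight order (ties by node id);
    each node joins at most one complex during prediction.  Complexes
    whose maximum internal core number is below ``k_core`` are
    discarded.  Output is sorted by score descending.
    """
    params = params or MCODEParams()
    if net.number_of_nodes() == 0:
        return []
    weights = vertex_weights(net)
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    results: list[MCODEComplex] = []
    for seed in order:
        if seed in visited or net.degree(seed) < params.degree_cutoff:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        for _ in range(params.max_depth):
            nxt = []
            for v in frontier:
                for u in sorted(net[v], key=str):
                    if u in visited or weights[u] <= threshold:
                        continue
                    members.add(u)
                    visited.add(u)
                    nxt.append(u)
            frontier = nxt
            if not frontier:
                break
        if params.haircut:
            members = set(haircut(members, net, seed=seed))
        if len(members) < 2:
            continue
        sub = net.subgraph(members)
        if max(core_decomposition(sub).values()) < params.k_core:
            continue
        if params.fluff:
            members = set(fluff(members, net, params.fluff_density_cutoff))
            sub = net.subgraph(members)
        results.append(
            MCODEComplex(
                members=frozenset(members),
                seed=seed,
                score=complex_score(sub.number_of_nodes(), sub.number_of_edges()),
                n_nodes=sub.number_of_nodes(),
                n_edges=sub.number_of_edges(),
            )
        )
    results.sort(key=lambda c: (-c.score, str(c.seed)))
    return results


def write_complexes_tsv(complexes: list[MCODEComplex], path) -> None:
    with open(path, "w") as handle:
        handle.write("rank\tscore\tn_nodes\tn_edges\tseed\tmembers\n")
        for rank, c in enumerate(complexes, start=1):
            members = ",".join(sorted(map(str, c.members)))
            handle.write(
                f"{rank}\t{c.score:.6g}\t{c.n_nodes}\t{c.n_edges}\t"
                f"{c.seed}\t{members}\n"
            )
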