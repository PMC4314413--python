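"""Independent brute-force oracles used to pin the fast implementations.

Everything here favors transparency over speed: explicit enumeration of
shortest paths, iterative deletion for core numbers, and exact binomial
arithmetic for hypergeometric tails.
"""

from itertools import combinations
from math import comb

import networkx as nx


def brute_centralities(g):
    """Stress, normalized betweenness and closeness by path enumeration."""
    nodes = sorted(g)
    n = len(nodes)
    stress = {v: 0 for v in nodes}
    betweenness = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            hits = sum(v in path for path in paths)
            stress[v] += hits
            betweenness[v] += hits / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        betweenness = {v: b / norm for v, b in betweenness.items()}
    else:
        betweenness = {v: 0.0 for v in nodes}
    closeness = {
        v: (n - 1) / sum(nx.shortest_path_length(g, v).values())
        for v in nodes
    }
    return stress, betweenness, closeness


def brute_core_numbers(g):
    """Core numbers by iterative deletion, one pass per k."""
    core = {v: 0 for v in g}
    degrees = dict(g.degree())
    for k in range(1, (max(degrees.values()) if degrees else 0) + 1):
        h = g.copy()
        while True:
            low = [v for v, d in h.degree() if d < k]
            if not low:
                break
            h.remove_nodes_from(low)
        for v in h:
            core[v] = k
    return core


def brute_vertex_weight(g, v):
    """Core-clustering coefficient evaluated straight from its definition."""
    sub = g.subgraph(set(g[v]) | {v})
    if sub.number_of_edges() == 0:
        return 0.0
    core = brute_core_numbers(sub)
    k_max = max(core.values())
    top = sub.subgraph([u for u, c in core.items() if c == k_max])
    n = top.number_of_nodes()
    density = 2 * top.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return k_max * density


def brute_hypergeom_tail(a, list_size, pathway_size, background):
    """P(X >= a) for X ~ Hypergeom(background, pathway_size, list_size)."""
    denom = comb(background, list_size)
    upper = min(list_size, pathway_size)
    total = sum(
        comb(pathway_size, x) * comb(background - pathway_size, list_size - x)
        for x in range(max(a, 0), upper + 1)
    )
    return total / denom


def random_connected_graph(rng, n_min=5, n_max=25):
    """A connected G(n, p) graph with string node labels."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.15, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n > 0 and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g})
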