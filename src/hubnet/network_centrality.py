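"""Interaction network construction and centrality analysis.

Graphs are simple and undirected; shortest paths are unweighted even
when edge confidence scores are present.  Stress and betweenness are
computed with a Brandes-style single-source accumulation; their
correctness is pinned by exhaustive path-enumeration oracles in the test
suite.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable, Sequence
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "parse_edge_list",
    "build_network",
    "giant_component",
    "degree",
    "stress_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_table",
    "write_edge_list",
]

_HEADER_NAMES = {
    "protein1", "protein2", "node1", "node2", "nodea", "nodeb",
    "source", "target", "gene1", "gene2",
}


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list lines; carries the line number."""


def _is_header(fields: Sequence[str]) -> bool:
    if fields[0].strip().lower() in _HEADER_NAMES:
        return True
    if len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def parse_edge_list(path) -> list[tuple[str, str, float | None]]:
    """Parse a 2- or 3-column (STRING-export style) edge-list file.

    The optional third column is a confidence score.  A header line is
    auto-detected and skipped.
    """
    edges: list[tuple[str, str, float | None]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split()
            if lineno == 1 and _is_header(fields):
                continue
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=2 columns, got {len(fields)}"
                )
            score: float | None = None
            if len(fields) >= 3:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: bad score field {fields[2]!r}"
                    ) from exc
            edges.append((fields[0], fields[1], score))
    return edges


def build_network(
    edges: str | Path | Iterable[tuple],
    restrict_to_genes: Iterable[str] | None = None,
    score_cutoff: float | None = None,
) -> nx.Graph:
    """Build a simple undirected graph from an edge list or file.

    Self-loops are dropped and duplicate edges merged (keeping the max
    score).  With ``restrict_to_genes`` only edges between listed genes
    are kept; with ``score_cutoff`` only edges scoring at least the
    cutoff (edges without a score always pass).
    """
    if isinstance(edges, (str, Path)):
        edges = parse_edge_list(edges)
    allowed = set(restrict_to_genes) if restrict_to_genes is not None else None
    g = nx.Graph()
    for edge in edges:
        u, v = edge[0], edge[1]
        score = edge[2] if len(edge) > 2 else None
        if u == v:
            continue
        if allowed is not None and (u not in allowed or v not in allowed):
            continue
        if score_cutoff is not None and score is not None and score < score_cutoff:
            continue
        if g.has_edge(u, v):
            old = g[u][v].get("score")
            if score is not None and (old is None or score > old):
                g[u][v]["score"] = score
        else:
            g.add_edge(u, v, score=score)
    return g


def giant_component(net: nx.Graph) -> nx.Graph:
    """Return the largest connected component (ties: smallest member id)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph has no giant component")
    components = sorted(
        nx.connected_components(net), key=lambda c: (-len(c), min(map(str, c)))
    )
    return net.subgraph(components[0]).copy()


def degree(net: nx.Graph) -> dict[str, int]:
    return dict(net.degree())


def _require_connected(net: nx.Graph) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(net):
        raise ValueError(
            "graph is disconnected; extract the giant component first"
        )


def _brandes(net: nx.Graph) -> tuple[dict, dict]:
    """Single-source accumulation of raw betweenness and stress.

    Returns per-node sums over ordered (s, t) pairs with endpoints
    excluded; divide by two for unordered-pair counting.
    """
    betweenness = dict.fromkeys(net, 0.0)
    stress = dict.fromkeys(net, 0.0)
    nodes = sorted(net.nodes, key=str)
    for s in nodes:
        stack: list = []
        preds: dict = {v: [] for v in net}
        sigma = dict.fromkeys(net, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(net, 0.0)
        # paths_down[v]: number of shortest paths from v to targets below it
        paths_down = dict.fromkeys(net, 0.0)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
                paths_down[v] += 1.0 + paths_down[w]
            if w != s:
                betweenness[w] += delta[w]
                stress[w] += sigma[w] * paths_down[w]
    return betweenness, stress


def stress_centrality(net: nx.Graph, ordered: bool = False) -> dict[str, int]:
    """Number of shortest paths between other node pairs passing through v.

    Unordered source-target pairs by default; ``ordered=True`` doubles
    every value (the convention of some other tools).
    """
    _require_connected(net)
    _, stress = _brandes(net)
    scale = 1.0 if ordered else 0.5
    return {v: int(round(x * scale)) for v, x in stress.items()}


def betweenness_centrality(
    net: nx.Graph, normalized: bool = True
) -> dict[str, float]:
    """Fraction-of-shortest-paths betweenness over unordered pairs.

    Normalized by (N-1)(N-2)/2 so values lie in [0, 1]; graphs with
    fewer than three nodes get all zeros.
    """
    _require_connected(net)
    raw, _ = _brandes(net)
    n = net.number_of_nodes()
    if normalized:
        if n < 3:
            return dict.fromkeys(net, 0.0)
        scale = 1.0 / ((n - 1) * (n - 2))
    else:
        scale = 0.5
    return {v: x * scale for v, x in raw.items()}


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """(N-1) / (sum of shortest-path distances); larger is more central."""
    _require_connected(net)
    n = net.number_of_nodes()
    if n == 1:
        return dict.fromkeys(net, 0.0)
    out = {}
    for v in net:
        total = sum(nx.single_source_shortest_path_length(net, v).values())
        out[v] = (n - 1) / total
    return out


def centrality_table(net: nx.Graph, stress_ordered: bool = False) -> pd.DataFrame:
    """All four centralities on a connected graph, sorted by degree desc."""
    _require_connected(net)
    table = pd.DataFrame(
        {
            "degree": pd.Series(degree(net)),
            "stress": pd.Series(stress_centrality(net, ordered=stress_ordered)),
            "betweenness": pd.Series(betweenness_centrality(net)),
            "closeness": pd.Series(closeness_centrality(net)),
        }
    )
    table.index.name = "node"
    table = table.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    )
    return table


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a three-column STRING-style edge list (missing scores blank)."""
    with open(path, "w") as handle:
        handle.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            score = net[u][v].get("score")
            text = "" if score is None else f"{score:g}"
            handle.write(f"{u}\t{v}\t{text}\n")
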