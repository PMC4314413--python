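"""Group-level centrality comparison and hub-subnetwork extraction.

Clusters and enriched pathways are compared per centrality with two-group
one-way ANOVA (equivalent to a pooled-variance t-test squared); the hub
subnetwork is the exact intersection of the selected groups, with its
induced edges.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CENTRALITIES",
    "GroupCentralitySummary",
    "HubSubnetwork",
    "group_centralities",
    "pairwise_anova",
    "select_significant_groups",
    "hub_subnetwork",
    "top_hubs",
]

logger = logging.getLogger(__name__)

CENTRALITIES = ("degree", "stress", "betweenness", "closeness")


@dataclass
class GroupCentralitySummary:
    group: str
    members: frozenset
    values: dict[str, np.ndarray]
    means: dict[str, float]


@dataclass
class HubSubnetwork:
    source_groups: tuple[str, ...]
    hub_genes: frozenset
    induced_edges: frozenset  # of sorted 2-tuples
    pairwise: dict[tuple[str, str], frozenset] = field(default_factory=dict)


def group_centralities(
    table: pd.DataFrame, groups: Mapping[str, Iterable[str]]
) -> list[GroupCentralitySummary]:
    """Per-group centrality value vectors and means.

    Group members missing from the centrality table are dropped with a
    log message; groups left empty are excluded with a warning.
    """
    nodes = set(table.index)
    out = []
    for name in sorted(groups):
        members = set(groups[name])
        present = members & nodes
        if len(present) < len(members):
            logger.info(
                "group %s: dropped %d members absent from the table",
                name, len(members) - len(present),
            )
        if not present:
            logger.warning("group %s has no members in the table; skipped", name)
            continue
        sub = table.loc[sorted(present)]
        values = {c: sub[c].to_numpy(dtype=float) for c in CENTRALITIES}
        means = {c: float(v.mean()) for c, v in values.items()}
        out.append(
            GroupCentralitySummary(
                group=name, members=frozenset(present),
                values=values, means=means,
            )
        )
    return out


def _two_group_anova(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups (F equals pooled t squared)."""
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def pairwise_anova(
    summaries: list[GroupCentralitySummary],
    alphas: tuple[float, ...] = (0.05, 0.01, 0.0001),
) -> pd.DataFrame:
    """Two-group one-way ANOVA for every unordered group pair and centrality.

    The ``stars`` column holds one star per significance level met
    (strict <), from the loosest to the tightest alpha.
    """
    levels = sorted(alphas, reverse=True)
    rows = []
    for a, b in combinations(summaries, 2):
        for centrality in CENTRALITIES:
            va, vb = a.values[centrality], b.values[centrality]
            if len(va) < 2 or len(vb) < 2:
                continue
            f, p = _two_group_anova(va, vb)
            stars = "*" * sum(p < alpha for alpha in levels)
            rows.append(
                {
                    "group_a": a.group,
                    "group_b": b.group,
                    "centrality": centrality,
                    "F": f,
                    "p": p,
                    "stars": stars,
                }
            )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "centrality", "F", "p", "stars"]
    )


def select_significant_groups(
    cluster_summaries: list[GroupCentralitySummary],
    comparisons: pd.DataFrame,
    pathway_summaries: list[GroupCentralitySummary],
    enrichment: pd.DataFrame,
    alpha: float = 0.05,
    p01: float = 0.01,
    top_k_pathways: int = 2,
) -> tuple[str | None, list[str]]:
    """Pick the hub-defining groups.

    Cluster: the highest-mean-degree cluster that differs significantly
    (degree ANOVA p < alpha) from at least one other cluster; a lone
    cluster qualifies by default.  Pathways: the top-tier (EASE p < p01)
    pathways with the highest mean degree, at most ``top_k_pathways``.
    """
    chosen_cluster: str | None = None
    ordered = sorted(
        cluster_summaries, key=lambda s: (-s.means["degree"], s.group)
    )
    if len(ordered) == 1:
        chosen_cluster = ordered[0].group
    else:
        cluster_names = {s.group for s in cluster_summaries}
        deg = comparisons[
            (comparisons["centrality"] == "degree")
            & comparisons["group_a"].isin(cluster_names)
            & comparisons["group_b"].isin(cluster_names)
        ]
        for summary in ordered:
            mine = deg[
                (deg["group_a"] == summary.group)
                | (deg["group_b"] == summary.group)
            ]
            if (mine["p"] < alpha).any():
                chosen_cluster = summary.group
                break
    if chosen_cluster is None and cluster_summaries:
        logger.warning("no cluster passed the significance rule")

    top_tier = set(enrichment.loc[enrichment["ease_p"] < p01, "term"])
    candidates = [s for s in pathway_summaries if s.group in top_tier]
    candidates.sort(key=lambda s: (-s.means["degree"], s.group))
    chosen_pathways = [s.group for s in candidates[:top_k_pathways]]
    return chosen_cluster, chosen_pathways


def hub_subnetwork(
    groups: Mapping[str, Iterable[str]], net: nx.Graph
) -> HubSubnetwork:
    """Intersect all group member sets and induce the hub subnetwork.

    Also reports every pairwise intersection.  An empty intersection is
    valid and logged.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups to intersect")
    names = sorted(groups)
    sets = {name: frozenset(groups[name]) for name in names}
    hub: frozenset = sets[names[0]]
    for name in names[1:]:
        hub &= sets[name]
    if not hub:
        logger.info("group intersection is empty")
    sub = net.subgraph(hub & set(net.nodes))
    edges = frozenset(tuple(sorted(e)) for e in sub.edges)
    pairwise = {
        (a, b): sets[a] & sets[b] for a, b in combinations(names, 2)
    }
    return HubSubnetwork(
        source_groups=tuple(names),
        hub_genes=hub,
        induced_edges=edges,
        pairwise=pairwise,
    )


def top_hubs(
    table: pd.DataFrame, k: int
) -> tuple[dict[str, list[tuple[str, float]]], set[str]]:
    """Top-k nodes per centrality (ties lexicographic) and their overlap.

    Returns the four ranked lists and the set of nodes present in all
    of them; ``k`` beyond the node count truncates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lists: dict[str, list[tuple[str, float]]] = {}
    for centrality in CENTRALITIES:
        ranked = table[centrality].sort_index().sort_values(
            ascending=False, kind="mergesort"
        )
        lists[centrality] = [
            (node, float(value)) for node, value in ranked.head(k).items()
        ]
    common = set.intersection(
        *({node for node, _ in lists[c]} for c in CENTRALITIES)
    )
    return lists, common
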