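"""Synthetic multi-study expression data, networks and pathway sets.

Every generator has known planted structure (differential genes, dense
cliques, one enriched pathway) so the whole pipeline can be validated
offline.  A single seed drives independent substreams per generator, so
adding a generator call never perturbs earlier outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .pathway_enrichment import PathwayCollection
from .signature_scoring import ExpressionStudy

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gene_universe",
    "generate_studies",
    "generate_network",
    "generate_pathways",
    "write_expression_tsv",
    "write_labels_tsv",
    "write_truth",
    "read_truth",
]

# substream ids: one per generator
_STUDIES, _NETWORK, _PATHWAYS = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation."""

    n_studies: int = 5
    m_genes: int = 500
    samples_per_group: int = 10
    n_de_genes: int = 20
    effect_size: float = 3.0
    noise_sd: float = 0.5
    clique_sizes: tuple[int, ...] = (8,)
    background_edge_param: int = 2
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 40)
    planted_pathway_overlap: int = 10
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clique_sizes", tuple(self.clique_sizes))
        object.__setattr__(
            self, "pathway_size_range", tuple(self.pathway_size_range)
        )
        for name in ("n_studies", "m_genes", "samples_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.m_genes:
            raise ValueError("n_de_genes must lie in [0, m_genes]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(k < 4 for k in self.clique_sizes):
            raise ValueError("every planted clique needs >=4 nodes")
        if sum(self.clique_sizes) > self.m_genes:
            raise ValueError("planted cliques exceed the gene universe")
        if self.background_edge_param < 1:
            raise ValueError("background_edge_param must be >=1")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be nonnegative")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max")
        if hi > self.m_genes:
            raise ValueError("pathway sizes exceed the gene universe")
        if self.planted_pathway_overlap > self.n_de_genes:
            raise ValueError("planted_pathway_overlap exceeds n_de_genes")


@dataclass
class GroundTruth:
    """Planted structure of one simulation."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> +-1
    clique_members: list[set] = field(default_factory=list)
    enriched_pathway: str | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream,))
    )


def gene_universe(config: SimulationConfig) -> list[str]:
    """Gene ids ``G0001..`` — zero-padded, so lexicographic = numeric order."""
    width = len(str(config.m_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.m_genes + 1)]


def generate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate case/control studies over a shared gene universe.

    Planted genes have their case-group mean shifted by the signed
    effect size in every study; all values are independent Gaussians on
    the log2 scale around per-gene baselines shared across studies.
    """
    rng = _rng(config, _STUDIES)
    genes = gene_universe(config)
    m, k = config.m_genes, config.samples_per_group

    de_idx = rng.choice(m, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1, 1], size=config.n_de_genes)
    shift = np.zeros(m)
    shift[de_idx] = signs * config.effect_size
    baseline = rng.normal(config.baseline_mean, 1.0, size=m)

    studies = []
    for j in range(1, config.n_studies + 1):
        sid = f"S{j}"
        noise = rng.normal(0.0, config.noise_sd, size=(m, 2 * k))
        values = baseline[:, None] + noise
        values[:, :k] += shift[:, None]
        columns = [f"{sid}_case_{i}" for i in range(1, k + 1)] + [
            f"{sid}_ctrl_{i}" for i in range(1, k + 1)
        ]
        frame = pd.DataFrame(values, index=genes, columns=columns)
        frame.index.name = "gene"
        groups = ["case"] * k + ["control"] * k
        studies.append(ExpressionStudy(sid, frame, groups, weight=1.0))

    truth = GroundTruth(
        de_genes={genes[i]: int(s) for i, s in zip(de_idx, signs)}
    )
    return studies, truth


def generate_network(
    config: SimulationConfig,
    gene_universe: list[str],
    truth: GroundTruth | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Background preferential-attachment graph plus planted cliques.

    Clique members are drawn preferentially from the planted
    differential genes (when a truth is supplied) so that the
    signature -> network -> cluster chain carries signal.  Edges get
    STRING-style confidence scores in [150, 999].
    """
    if sum(config.clique_sizes) > len(gene_universe):
        raise ValueError("planted cliques exceed the gene universe")
    truth = truth or GroundTruth()
    rng = _rng(config, _NETWORK)

    n = len(gene_universe)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    background = nx.barabasi_albert_graph(
        n, config.background_edge_param, seed=ba_seed
    )
    net = nx.relabel_nodes(
        background, {i: gene_universe[i] for i in range(n)}
    )
    for u, v in net.edges:
        net[u][v]["score"] = int(rng.integers(150, 700))

    de_pool = [g for g in sorted(truth.de_genes) if g in set(gene_universe)]
    other_pool = [g for g in gene_universe if g not in set(de_pool)]
    rng.shuffle(de_pool)
    rng.shuffle(other_pool)
    pool = de_pool + other_pool  # planted genes first

    truth.clique_members = []
    cursor = 0
    for size in config.clique_sizes:
        members = pool[cursor : cursor + size]
        cursor += size
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                score = int(rng.integers(700, 1000))
                if net.has_edge(u, v):
                    net[u][v]["score"] = max(net[u][v]["score"], score)
                else:
                    net.add_edge(u, v, score=score)
        truth.clique_members.append(set(members))
    return net, truth


def generate_pathways(
    config: SimulationConfig,
    gene_universe: list[str],
    truth: GroundTruth | None = None,
) -> tuple[PathwayCollection, GroundTruth]:
    """Random gene sets with one planted enriched pathway.

    The planted pathway contains ``planted_pathway_overlap`` planted
    differential genes (preferring genes inside planted cliques); the
    rest of every pathway is filled uniformly at random.
    """
    truth = truth or GroundTruth()
    rng = _rng(config, _PATHWAYS)
    if config.n_pathways == 0:
        return PathwayCollection(), truth

    lo, hi = config.pathway_size_range
    width = len(str(max(config.n_pathways, 1)))
    names = [f"PW{i:0{width}d}" for i in range(1, config.n_pathways + 1)]
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)

    universe = np.array(gene_universe)
    pathways: dict[str, frozenset] = {}

    planted_name = names[0]
    overlap = config.planted_pathway_overlap
    if overlap > sizes[0]:
        raise ValueError(
            "planted_pathway_overlap exceeds the planted pathway size"
        )
    in_cliques = set().union(*truth.clique_members) if truth.clique_members else set()
    de_in_cliques = sorted(set(truth.de_genes) & in_cliques)
    de_rest = sorted(set(truth.de_genes) - in_cliques)
    preferred = de_in_cliques + de_rest
    if overlap > len(preferred):
        raise ValueError("not enough planted genes for the requested overlap")
    chosen = preferred[:overlap]
    # exclude every planted gene from the filler so the overlap is exact
    filler_pool = [g for g in gene_universe if g not in truth.de_genes]
    n_fill = int(sizes[0]) - overlap
    fill = rng.choice(len(filler_pool), size=n_fill, replace=False)
    pathways[planted_name] = frozenset(chosen) | frozenset(
        filler_pool[i] for i in fill
    )

    for name, size in zip(names[1:], sizes[1:]):
        idx = rng.choice(len(universe), size=int(size), replace=False)
        pathways[name] = frozenset(universe[idx])

    truth.enriched_pathway = planted_name
    return PathwayCollection(pathways=pathways), truth


def write_expression_tsv(study: ExpressionStudy, path) -> None:
    study.values.to_csv(path, sep="\t", float_format="%.6f")


def write_labels_tsv(study: ExpressionStudy, path) -> None:
    with open(path, "w") as handle:
        handle.write("sample\tgroup\n")
        for sample, group in study.groups.items():
            handle.write(f"{sample}\t{group}\n")


def write_truth(truth: GroundTruth, path) -> None:
    payload = asdict(truth)
    payload["clique_members"] = [sorted(c) for c in truth.clique_members]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_truth(path) -> GroundTruth:
    with open(path) as handle:
        payload = json.load(handle)
    return GroundTruth(
        de_genes={g: int(s) for g, s in payload["de_genes"].items()},
        clique_members=[set(c) for c in payload["clique_members"]],
        enriched_pathway=payload.get("enriched_pathway"),
    )
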