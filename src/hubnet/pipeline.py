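"""Pipeline orchestration: configuration, stages, and the run manifest.

Stages exchange plain TSV/GMT/JSON files inside the output directory so
each one is independently runnable, diffable and idempotent.  The
manifest records the config hash, seed, package version and row counts,
which is enough to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import hub_analysis as ha
from . import mcode_clustering as mc
from . import network_centrality as nc
from . import pathway_enrichment as pe
from . import signature_scoring as ss
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_all", "STAGES"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    outdir: str = "hubnet_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: sd.SimulationConfig | None = field(
        default_factory=sd.SimulationConfig
    )
    studies: list[dict] = field(default_factory=list)
    network_path: str | None = None
    pathways_path: str | None = None
    weights: list[float] | None = None
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    score_cutoff: float | None = None
    stress_ordered: bool = False
    mcode: mc.MCODEParams = field(default_factory=mc.MCODEParams)
    enrich_p05: float = 0.05
    enrich_p01: float = 0.01
    anova_alpha: float = 0.05
    top_k_pathways: int = 2

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = sd.SimulationConfig(**self.simulate)
        if isinstance(self.mcode, dict):
            self.mcode = mc.MCODEParams(**self.mcode)
        for name in ("fc_threshold", "p_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # where a run lives is not what it is
        payload.pop("log_level", None)
        canonical = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_studies(config: PipelineConfig, out: Path) -> list[ss.ExpressionStudy]:
    if config.studies:
        return [
            ss.read_expression_tsv(
                entry["values"],
                entry["labels"],
                entry.get("id", f"S{i}"),
                float(entry.get("weight", 1.0)),
            )
            for i, entry in enumerate(config.studies, start=1)
        ]
    paths = sorted(out.glob("study_*_values.tsv"))
    if not paths:
        raise ConfigError(
            "no 'studies' configured and no simulated studies found; "
            "set studies or enable simulate"
        )
    studies = []
    for values_path in paths:
        sid = values_path.name[len("study_") : -len("_values.tsv")]
        studies.append(
            ss.read_expression_tsv(
                values_path, out / f"study_{sid}_labels.tsv", sid
            )
        )
    return studies


def _network_path(config: PipelineConfig, out: Path) -> Path:
    if config.network_path:
        return Path(config.network_path)
    candidate = out / "network_edges.tsv"
    if candidate.exists():
        return candidate
    raise ConfigError(
        "network_path is not set and no simulated network was found"
    )


def _pathways_path(config: PipelineConfig, out: Path) -> Path:
    if config.pathways_path:
        return Path(config.pathways_path)
    candidate = out / "pathways.gmt"
    if candidate.exists():
        return candidate
    raise ConfigError(
        "pathways_path is not set and no simulated pathway file was found"
    )


def stage_simulate(config: PipelineConfig) -> dict:
    if config.simulate is None:
        raise ConfigError("simulate stage requested but 'simulate' is null")
    out = _outdir(config)
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    studies, truth = sd.generate_studies(sim)
    universe = sd.gene_universe(sim)
    net, truth = sd.generate_network(sim, universe, truth)
    pathways, truth = sd.generate_pathways(sim, universe, truth)
    for study in studies:
        sd.write_expression_tsv(study, out / f"study_{study.study_id}_values.tsv")
        sd.write_labels_tsv(study, out / f"study_{study.study_id}_labels.tsv")
    nc.write_edge_list(net, out / "network_edges.tsv")
    pe.write_gmt(pathways, out / "pathways.gmt")
    sd.write_truth(truth, out / "truth.json")
    return {
        "studies": len(studies),
        "genes": sim.m_genes,
        "network_edges": net.number_of_edges(),
        "pathways": len(pathways),
    }


def stage_signatures(config: PipelineConfig) -> dict:
    out = _outdir(config)
    studies = _load_studies(config, out)
    table = ss.score_table(
        studies,
        weights=config.weights,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
    )
    ss.write_score_table(table, out / "scores.tsv")
    selected = table[table["selected"]]
    selected[["direction"]].to_csv(out / "signatures.tsv", sep="\t")
    return {
        "common_genes": len(table),
        "signatures": int(table["selected"].sum()),
        "up": int((selected["direction"] == "up").sum()),
        "down": int((selected["direction"] == "down").sum()),
    }


def _read_signatures(out: Path) -> list[str]:
    path = out / "signatures.tsv"
    if not path.exists():
        raise ConfigError("signatures.tsv not found; run the signatures stage")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return list(frame.index)


def stage_network(config: PipelineConfig) -> dict:
    out = _outdir(config)
    genes = _read_signatures(out)
    net = nc.build_network(
        _network_path(config, out),
        restrict_to_genes=genes,
        score_cutoff=config.score_cutoff,
    )
    if net.number_of_nodes() == 0:
        raise StageError("network stage: no edges among the signature genes")
    giant = nc.giant_component(net)
    nc.write_edge_list(giant, out / "giant_edges.tsv")
    table = nc.centrality_table(giant, stress_ordered=config.stress_ordered)
    table.to_csv(out / "centrality.tsv", sep="\t", float_format="%.10g")
    return {
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
        "giant_nodes": giant.number_of_nodes(),
        "giant_edges": giant.number_of_edges(),
    }


def stage_mcode(config: PipelineConfig) -> dict:
    out = _outdir(config)
    path = out / "giant_edges.tsv"
    if not path.exists():
        raise ConfigError("giant_edges.tsv not found; run the network stage")
    net = nc.build_network(path)
    complexes = mc.predict_complexes(net, config.mcode)
    mc.write_complexes_tsv(complexes, out / "complexes.tsv")
    return {"complexes": len(complexes)}


def stage_enrich(config: PipelineConfig) -> dict:
    out = _outdir(config)
    genes = _read_signatures(out)
    collection = pe.read_gmt(_pathways_path(config, out))
    result = pe.enrich(
        genes, collection, p05=config.enrich_p05, p01=config.enrich_p01
    )
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return {
        "tested_pathways": len(result),
        "p01_pathways": int((result["tier"] == "p01").sum()) if len(result) else 0,
    }


def _read_complex_groups(out: Path) -> dict[str, set]:
    path = out / "complexes.tsv"
    if not path.exists():
        raise ConfigError("complexes.tsv not found; run the mcode stage")
    frame = pd.read_csv(path, sep="\t")
    return {
        f"cluster{int(row['rank'])}": set(str(row["members"]).split(","))
        for _, row in frame.iterrows()
    }


def stage_hub(config: PipelineConfig) -> dict:
    out = _outdir(config)
    centrality_path = out / "centrality.tsv"
    if not centrality_path.exists():
        raise ConfigError("centrality.tsv not found; run the network stage")
    table = pd.read_csv(centrality_path, sep="\t", index_col=0)
    enrichment_path = out / "enrichment.tsv"
    if not enrichment_path.exists():
        raise ConfigError("enrichment.tsv not found; run the enrich stage")
    enrichment = pd.read_csv(enrichment_path, sep="\t")

    clusters = _read_complex_groups(out)
    collection = pe.read_gmt(_pathways_path(config, out))
    top_tier = (
        set(enrichment.loc[enrichment["ease_p"] < config.enrich_p01, "term"])
        if len(enrichment)
        else set()
    )
    pathway_groups = {
        name: set(collection[name]) for name in sorted(top_tier)
    }

    cluster_summaries = ha.group_centralities(table, clusters)
    pathway_summaries = ha.group_centralities(table, pathway_groups)
    comparisons = ha.pairwise_anova(cluster_summaries + pathway_summaries)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                       float_format="%.6g")

    rows = [
        {
            "group": s.group,
            "n": len(s.members),
            **{f"mean_{c}": s.means[c] for c in ha.CENTRALITIES},
            "members": ",".join(sorted(s.members)),
        }
        for s in cluster_summaries + pathway_summaries
    ]
    pd.DataFrame(rows).to_csv(out / "groups.tsv", sep="\t", index=False,
                              float_format="%.6g")

    cluster, pathways = ha.select_significant_groups(
        cluster_summaries,
        comparisons,
        pathway_summaries,
        enrichment,
        alpha=config.anova_alpha,
        p01=config.enrich_p01,
        top_k_pathways=config.top_k_pathways,
    )
    chosen: dict[str, set] = {}
    by_name = {s.group: s for s in cluster_summaries + pathway_summaries}
    if cluster is not None:
        chosen[cluster] = set(by_name[cluster].members)
    for name in pathways:
        chosen[name] = set(by_name[name].members)

    net = nc.build_network(out / "giant_edges.tsv")
    if len(chosen) >= 2:
        hub = ha.hub_subnetwork(chosen, net)
        hub_genes = sorted(hub.hub_genes)
        hub_edges = sorted(hub.induced_edges)
    else:
        logger.warning("fewer than two significant groups; hub is empty")
        hub_genes, hub_edges = [], []

    with open(out / "hub_nodes.tsv", "w") as handle:
        handle.write("gene\n")
        for gene in hub_genes:
            handle.write(f"{gene}\n")
    with open(out / "hub_edges.tsv", "w") as handle:
        handle.write("protein1\tprotein2\n")
        for u, v in hub_edges:
            handle.write(f"{u}\t{v}\n")
    return {
        "selected_cluster": cluster or "",
        "selected_pathways": ",".join(pathways),
        "hub_genes": len(hub_genes),
        "hub_edges": len(hub_edges),
    }


STAGES = {
    "simulate": stage_simulate,
    "signatures": stage_signatures,
    "network": stage_network,
    "mcode": stage_mcode,
    "enrich": stage_enrich,
    "hub": stage_hub,
}


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and write the run manifest.

    The simulate stage is skipped when ``simulate`` is null in the
    config.  Any stage failure raises a :class:`StageError` naming the
    stage; outputs of earlier stages are retained.
    """
    out = _outdir(config)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "counts": {},
    }
    names = list(STAGES)
    if config.simulate is None:
        names.remove("simulate")
    for name in names:
        logger.info("running stage %s", name)
        try:
            manifest["counts"][name] = STAGES[name](config)
        except ConfigError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
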