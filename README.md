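# hubnet

Hub-subnetwork discovery from multi-study case/control gene-expression
data.  The pipeline chains six stages:

1. **signature_scoring** — per-study log2 fold changes, Welch t-test
   p-values, rank-based GWRS scores (`-2 ln(r/m)`), the weighted
   cross-study GWGS combination, maxP p-value combination, and the
   `|log2FC| > 2 & p < 0.01` signature filter.
2. **network_centrality** — builds a simple undirected interaction
   network from a STRING-style edge list restricted to the signature
   genes, extracts the giant component, and computes degree, stress,
   betweenness and closeness centralities (Brandes-style accumulation,
   verified against exhaustive path-enumeration oracles).
3. **mcode_clustering** — a full MCODE re-implementation: k-core
   decomposition, core-clustering-coefficient vertex weighting, seeded
   complex prediction, optional haircut/fluff post-processing, and
   density x size complex scoring.
4. **pathway_enrichment** — EASE-score (jackknifed one-sided Fisher)
   enrichment of the signature set against local GMT pathway
   collections, with strict 0.05/0.01 significance tiers and an
   informational Benjamini-Hochberg column.
5. **hub_analysis** — per-group centrality summaries, pairwise two-group
   one-way ANOVA, selection of the top cluster and top pathways, and the
   hub subnetwork as their exact intersection with induced edges.
6. **synthetic_data** — deterministic generators for multi-study
   expression matrices with planted differential genes, a
   preferential-attachment background network with planted cliques, and
   pathway collections with one planted enriched set, so every stage is
   testable offline.

## CLI

Every stage is a subcommand reading/writing plain TSV/GMT/JSON files in
the output directory; `run-all` chains them and writes a `manifest.json`
with the config hash, seed, and per-stage row counts:

```sh
hubnet run-all --config config.yaml --seed 1 --out out/
hubnet simulate   --out out/            # synthetic inputs only
hubnet signatures --out out/            # score table + signature list
hubnet network    --config config.yaml  # giant component + centralities
hubnet mcode      --out out/            # complexes.tsv
hubnet enrich     --config config.yaml  # enrichment.tsv
hubnet hub        --config config.yaml  # groups, comparisons, hub subnetwork
```

With no config, `run-all` uses the default synthetic scenario.  A config
is a YAML mapping of the `PipelineConfig` fields, e.g.

```yaml
outdir: out
seed: 1
simulate: {m_genes: 500, n_de_genes: 20, clique_sizes: [8]}
# or, for real inputs:
# simulate: null
# studies: [{values: s1.tsv, labels: s1_labels.tsv, id: S1, weight: 1.0}]
# network_path: string_edges.tsv
# pathways_path: pathways.gmt
mcode: {k_core: 4, node_score_cutoff: 0.3, max_depth: 100}
```

File formats: expression tables are genes x samples TSV with a header of
sample ids; labels are two-column TSV (sample, group with values
`case`/`control`); networks are 2-3 column edge lists (optional
confidence score, header auto-detected); pathways are standard GMT.

Per-study tests use Welch's t-test on the log2 values, so absolute
p-values will differ from analyses based on moderated-variance models;
the rank-based scores are unaffected by monotone differences.

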