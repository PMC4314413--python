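"""Cross-study gene signature scoring.

Per study: log2 fold change, a Welch t-test p-value, and a rank-based
genome-wide relative significance (GWRS) score.  Across studies: the
weighted genome-wide global significance (GWGS) score, mean log2FC and
the maxP-combined p-value, followed by the |log2FC|/p selection filter.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionStudy",
    "collapse_probes",
    "filter_common_genes",
    "fold_change",
    "per_study_pvalue",
    "rank_genes",
    "gwrs",
    "gwgs",
    "maxp_combine",
    "score_table",
    "select_signatures",
    "read_expression_tsv",
    "write_score_table",
]

CASE = "case"
CONTROL = "control"

_P_FLOOR = 1e-300  # p-values are kept strictly positive


@dataclass
class ExpressionStudy:
    """One study's log2 gene-by-sample matrix with group labels.

    Parameters
    ----------
    study_id:
        Short identifier used to name per-study output columns.
    values:
        ``genes x samples`` DataFrame of log2 expression values.
    groups:
        Per-sample label, ``"case"`` or ``"control"``, aligned with the
        columns of ``values``.
    weight:
        Nonnegative relative weight of the study; weights are normalized
        to sum to one across a study collection.
    """

    study_id: str
    values: pd.DataFrame
    groups: Sequence[str]
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.groups = pd.Series(list(self.groups), index=self.values.columns)
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in (CASE, CONTROL):
            if int((self.groups == label).sum()) < 2:
                raise ValueError(
                    f"study {self.study_id!r} needs >=2 {label} samples"
                )
        if self.values.index.has_duplicates:
            raise ValueError(f"study {self.study_id!r} has duplicate gene ids")
        if self.weight < 0:
            raise ValueError("study weight must be nonnegative")

    @property
    def case_values(self) -> pd.DataFrame:
        return self.values.loc[:, (self.groups == CASE).to_numpy()]

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values.loc[:, (self.groups == CONTROL).to_numpy()]

    def restrict(self, genes: Sequence[str]) -> "ExpressionStudy":
        """Return a copy restricted to ``genes`` in the given order."""
        return ExpressionStudy(
            study_id=self.study_id,
            values=self.values.loc[list(genes)],
            groups=list(self.groups),
            weight=self.weight,
        )


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, str | Sequence[str]],
) -> pd.DataFrame:
    """Collapse a probe-by-sample matrix to gene level by element-wise max.

    A probe mapped to several genes contributes to each of them; probes
    absent from the map are dropped.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene map is empty")
    gene_probes: dict[str, list[str]] = {}
    for probe, genes in probe_to_gene.items():
        if probe not in probe_matrix.index:
            continue
        if isinstance(genes, str):
            genes = [genes]
        for gene in genes:
            gene_probes.setdefault(gene, []).append(probe)
    rows = {
        gene: probe_matrix.loc[probes].max(axis=0)
        for gene, probes in sorted(gene_probes.items())
    }
    out = pd.DataFrame(rows).T
    out.columns = probe_matrix.columns
    out.index.name = "gene"
    return out


def filter_common_genes(
    studies: Sequence[ExpressionStudy],
) -> tuple[list[str], list[ExpressionStudy]]:
    """Restrict studies to the genes present in every study.

    Returns the common gene list in lexicographic order and the studies
    restricted to it (same order as the input).
    """
    if len(studies) < 2:
        raise ValueError("need >=2 studies to intersect gene sets")
    common: set[str] = set(studies[0].values.index)
    for study in studies[1:]:
        common &= set(study.values.index)
    if not common:
        raise ValueError("studies share no genes; incompatible inputs")
    genes = sorted(common)
    return genes, [s.restrict(genes) for s in studies]


def fold_change(study: ExpressionStudy) -> pd.Series:
    """Per-gene log2 fold change: mean(case) - mean(control)."""
    fc = study.case_values.mean(axis=1) - study.control_values.mean(axis=1)
    fc.name = f"log2fc_{study.study_id}"
    return fc


def per_study_pvalue(study: ExpressionStudy) -> pd.Series:
    """Two-sided Welch t-test p-value per gene on the log2 values.

    Zero variance in both groups with equal means gives p = 1 by
    convention; p-values are clipped into (0, 1].
    """
    res = stats.ttest_ind(
        study.case_values.to_numpy(),
        study.control_values.to_numpy(),
        axis=1,
        equal_var=False,
    )
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0  # 0/0 statistic: identical constant groups
    p = np.clip(p, _P_FLOOR, 1.0)
    return pd.Series(p, index=study.values.index, name=f"p_{study.study_id}")


def rank_genes(
    log2fc: pd.Series, pvalues: pd.Series | None = None
) -> pd.Series:
    """Rank genes by decreasing |log2FC|; rank 1 is the largest.

    Ties are broken by the smaller p-value (when given), then by
    lexicographic gene id, so the result is a deterministic permutation
    of ``1..m``.
    """
    if pvalues is not None and not log2fc.index.equals(pvalues.index):
        raise ValueError("log2fc and pvalues must share the same gene index")
    frame = pd.DataFrame(
        {
            "absfc": log2fc.abs().to_numpy(),
            "p": pvalues.to_numpy() if pvalues is not None else 1.0,
            "gene": list(log2fc.index),
        }
    )
    order = frame.sort_values(
        ["absfc", "p", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
    ).index.to_numpy()
    ranks_arr = np.empty(len(order), dtype=int)
    ranks_arr[order] = np.arange(1, len(order) + 1)
    return pd.Series(ranks_arr, index=log2fc.index, name="rank")


def gwrs(rank: int | np.ndarray, m: int) -> float | np.ndarray:
    """Genome-wide relative significance of a rank among ``m`` genes.

    ``s = -2 ln(r/m)``: zero at the bottom rank, strictly decreasing in
    the rank number.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    r = np.asarray(rank, dtype=float)
    if np.any(r < 1) or np.any(r > m):
        raise ValueError("rank must lie in [1, m]")
    s = -2.0 * np.log(r / m)
    return float(s) if np.isscalar(rank) else s


def gwgs(
    scores: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
) -> float | np.ndarray:
    """Weighted combination of per-study GWRS scores.

    ``scores`` may be a vector (one score per study) or a
    ``genes x studies`` matrix.  Weights are normalized to sum to one.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or s.shape[1] != w.shape[0]:
        raise ValueError("one weight per study required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    combined = s @ (w / total)
    return float(combined[0]) if np.asarray(scores).ndim == 1 else combined


def maxp_combine(pvalues: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Combine per-study p-values by taking the maximum.

    Accepts a vector (one p per study) or a ``genes x studies`` matrix.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if p.ndim == 1:
        return float(p.max())
    return p.max(axis=1)


def score_table(
    studies: Sequence[ExpressionStudy],
    weights: Sequence[float] | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Build the full per-gene score table across studies.

    Columns: per-study ``log2fc_*``, ``p_*``, ``rank_*``, ``gwrs_*``,
    then ``gwgs``, ``mean_log2fc``, ``maxp``, ``selected`` and
    ``direction``.  Rows are indexed by gene, sorted by ``gwgs``
    descending (ties by gene id).
    """
    genes, restricted = filter_common_genes(studies)
    m = len(genes)
    if weights is None:
        weights = [s.weight for s in restricted]
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(restricted):
        raise ValueError("one weight per study required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()

    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gwrs_cols, fc_cols, p_cols = [], [], []
    for study in restricted:
        fc = fold_change(study)
        p = per_study_pvalue(study)
        ranks = rank_genes(fc, p)
        sid = study.study_id
        table[f"log2fc_{sid}"] = fc
        table[f"p_{sid}"] = p
        table[f"rank_{sid}"] = ranks
        table[f"gwrs_{sid}"] = gwrs(ranks.to_numpy(), m)
        gwrs_cols.append(f"gwrs_{sid}")
        fc_cols.append(f"log2fc_{sid}")
        p_cols.append(f"p_{sid}")

    table["gwgs"] = table[gwrs_cols].to_numpy() @ w
    table["mean_log2fc"] = table[fc_cols].mean(axis=1)
    table["maxp"] = maxp_combine(table[p_cols].to_numpy())
    table["selected"] = (table["mean_log2fc"].abs() > fc_threshold) & (
        table["maxp"] < p_threshold
    )
    direction = np.where(table["mean_log2fc"] > 0, "up", "down")
    table["direction"] = np.where(table["selected"], direction, "")
    table = table.sort_values(
        ["gwgs", "gene"], ascending=[False, True], kind="mergesort"
    )
    return table


def select_signatures(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Apply the signature filter and split into up/down gene sets.

    A gene is selected iff ``|mean_log2fc| > fc_threshold`` and
    ``maxp < p_threshold`` (both strict).
    """
    for col in ("mean_log2fc", "maxp"):
        if col not in table.columns:
            raise ValueError(f"score table lacks column {col!r}")
    keep = (table["mean_log2fc"].abs() > fc_threshold) & (
        table["maxp"] < p_threshold
    )
    up = set(table.index[keep & (table["mean_log2fc"] > 0)])
    down = set(table.index[keep & (table["mean_log2fc"] < 0)])
    return up, down


def read_expression_tsv(
    values_path, labels_path, study_id: str, weight: float = 1.0
) -> ExpressionStudy:
    """Read a study from a genes-x-samples TSV plus a two-column label TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    groups = labels.iloc[:, 0].reindex(values.columns)
    if groups.isna().any():
        missing = list(values.columns[groups.isna()])
        raise ValueError(f"samples missing group labels: {missing}")
    return ExpressionStudy(study_id, values, list(groups), weight)


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")
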