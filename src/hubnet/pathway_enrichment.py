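"""Pathway enrichment with the EASE score (jackknifed Fisher exact test).

Works against local GMT gene-set collections.  The EASE p-value is the
one-sided Fisher p of the 2x2 overlap table with the overlap count
reduced by one (margins fixed), a conservative penalty against
single-gene hits.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "ease_scores",
    "ease_p",
    "fisher_p",
    "enrich",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene sets plus an optional testing background."""

    pathways: dict[str, frozenset] = field(default_factory=dict)
    background: frozenset | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")

    def all_genes(self) -> frozenset:
        out: set = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset:
        return self.pathways[name]


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: one set per line (name, description, genes...)."""
    pathways: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            pathways[name] = genes
            descriptions[name] = description
    return PathwayCollection(pathways=pathways, descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as handle:
        for name in collection.pathways:
            desc = collection.descriptions.get(name, "na")
            genes = "\t".join(sorted(collection.pathways[name]))
            handle.write(f"{name}\t{desc}\t{genes}\n")


def _check_table(a: int, list_size: int, pathway_size: int, background: int) -> None:
    if not (0 <= a <= min(list_size, pathway_size)):
        raise ValueError("overlap exceeds a margin of the 2x2 table")
    if list_size > background or pathway_size > background:
        raise ValueError("margins exceed the background size")


def ease_scores(
    a: int, list_size: int, pathway_size: int, background: int
) -> tuple[float, float]:
    """EASE and plain one-sided Fisher p for an overlap table.

    Fisher: P(X >= a) under Hypergeom(background, pathway_size,
    list_size).  EASE: the same tail with the overlap count replaced by
    ``a - 1`` (margins unchanged); overlaps of 0 or 1 give p = 1.
    """
    _check_table(a, list_size, pathway_size, background)
    fisher = float(hypergeom.sf(a - 1, background, pathway_size, list_size))
    if a <= 1:
        ease = 1.0
    else:
        ease = float(hypergeom.sf(a - 2, background, pathway_size, list_size))
    return min(ease, 1.0), min(fisher, 1.0)


def ease_p(a: int, list_size: int, pathway_size: int, background: int) -> float:
    return ease_scores(a, list_size, pathway_size, background)[0]


def fisher_p(a: int, list_size: int, pathway_size: int, background: int) -> float:
    return ease_scores(a, list_size, pathway_size, background)[1]


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    n = len(pvalues)
    order = np.argsort(pvalues, kind="mergesort")
    ranked = pvalues[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich(
    gene_set: Iterable[str],
    collection: PathwayCollection,
    background: Iterable[str] | None = None,
    p05: float = 0.05,
    p01: float = 0.01,
) -> pd.DataFrame:
    """Test a gene set against every pathway in the collection.

    The default background is the union of the collection's gene sets
    (genes of the list absent from it are dropped, with a logged count).
    Rows cover pathways with overlap >= 1, sorted by EASE p ascending;
    tiers use strict thresholds.  A BH q-value column over the tested
    rows is included for information.
    """
    if background is not None:
        bg = frozenset(background)
    elif collection.background is not None:
        bg = collection.background
    else:
        bg = collection.all_genes()
    if not bg:
        raise ValueError("empty enrichment background")
    genes = set(gene_set)
    mapped = genes & bg
    dropped = len(genes) - len(mapped)
    if dropped:
        logger.info("%d genes not in the background were dropped", dropped)

    rows = []
    for name in sorted(collection.pathways):
        members = collection.pathways[name] & bg
        overlap = sorted(mapped & members)
        if not overlap:
            continue
        ease, fisher = ease_scores(
            len(overlap), len(mapped), len(members), len(bg)
        )
        rows.append(
            {
                "term": name,
                "count": len(overlap),
                "ease_p": ease,
                "fisher_p": fisher,
                "genes": ",".join(overlap),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term", "count", "ease_p", "fisher_p", "genes"]
    )
    if len(frame):
        frame["bh_q"] = _bh_adjust(frame["ease_p"].to_numpy())
        tier = np.where(
            frame["ease_p"] < p01, "p01",
            np.where(frame["ease_p"] < p05, "p05", "none"),
        )
        frame["tier"] = tier
        frame = frame.sort_values(
            ["ease_p", "term"], ascending=[True, True], kind="mergesort"
        ).reset_index(drop=True)
    else:
        frame["bh_q"] = pd.Series(dtype=float)
        frame["tier"] = pd.Series(dtype=str)
    return frame[["term", "count", "ease_p", "fisher_p", "bh_q", "tier", "genes"]]
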