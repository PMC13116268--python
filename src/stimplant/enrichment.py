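"""Over-representation analysis against user-supplied gene sets.

The statistic is the one-sided hypergeometric tail (equivalently a
one-sided Fisher exact test on the 2x2 overlap table): the probability of
observing at least the given overlap between the query and a set, given
the universe. By default the universe is the full gene panel of the count
matrix rather than the genome — in-situ panels are small and curated, so
the panel is the defensible null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stimplant.io_formats import StimplantError
from stimplant.clustering import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets (genes unique within a set) plus optional universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adj: float
    overlap_genes: list[str] = field(default_factory=list)


def hypergeom_tail(overlap: int, universe_size: int, set_size: int, query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set, query draws)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def overrepresentation(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query list against each set.

    Query genes outside the universe are dropped with a warning; set genes
    are intersected with the universe before testing. BH adjustment is
    applied across sets; output is sorted by p then set name.
    """
    if universe is None:
        universe = collection.universe
    if universe is None:
        raise StimplantError("no universe given and collection has none")
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    dropped = [g for g in q if g not in uni_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside universe dropped: {dropped[:5]}"
        )
    q = [g for g in q if g in uni_set]
    if not q:
        raise StimplantError("query is empty after intersecting with universe")
    q_set = set(q)
    rows = []
    for name in collection.sets:
        genes_in_uni = [g for g in collection.sets[name] if g in uni_set]
        overlap_genes = sorted(g for g in genes_in_uni if g in q_set)
        p = hypergeom_tail(len(overlap_genes), len(uni), len(genes_in_uni), len(q))
        rows.append(
            {
                "set_name": name,
                "overlap": len(overlap_genes),
                "set_size": len(genes_in_uni),
                "query_size": len(q),
                "universe_size": len(uni),
                "p_value": p,
                "overlap_genes": ",".join(overlap_genes),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return table.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def annotate_clusters(
    marker_tables: Mapping[int, pd.DataFrame] | Mapping[int, Sequence[str]],
    collection: GeneSetCollection,
    universe: Sequence[str] | None = None,
) -> tuple[dict[int, str], dict[int, pd.DataFrame]]:
    """Annotate each cluster with its best-matching gene set.

    ``marker_tables`` maps cluster -> marker table (with a ``gene`` column)
    or a plain gene list. The annotation is the smallest-p set; ties break
    to the larger overlap, then lexicographic name. All enrichment records
    are returned for audit.
    """
    annotations: dict[int, str] = {}
    records: dict[int, pd.DataFrame] = {}
    for cluster, markers in marker_tables.items():
        if isinstance(markers, pd.DataFrame):
            genes = list(markers["gene"])
        else:
            genes = list(markers)
        if not genes:
            raise StimplantError(f"cluster {cluster} has no markers")
        table = overrepresentation(genes, collection, universe)
        if len(table) == 0:
            raise StimplantError("gene set collection is empty")
        best = table.sort_values(
            ["p_value", "overlap", "set_name"], ascending=[True, False, True]
        ).iloc[0]
        annotations[int(cluster)] = str(best["set_name"])
        records[int(cluster)] = table
    return annotations, records
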