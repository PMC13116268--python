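"""Normalization, embedding, graph clustering, markers, DE, and frequencies.

The workflow is the standard single-cell recipe: median-library-size
normalization with log1p, PCA on standardized genes, a k-nearest-neighbor
graph in PC space, and Louvain community detection at a fixed resolution.
Marker detection applies an expression-fraction cutoff (fraction of
in-cluster cells with any detection, default 50%) and a log2 fold-change
cutoff (default 0.25) on de-logged normalized means with pseudocount 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from stimplant.io_formats import CountMatrix, StimplantError
from stimplant.qc_metrics import GroupComparison, compare_values


@dataclass
class ClusteringConfig:
    n_components: int = 15
    resolution: float = 0.8
    n_neighbors: int = 20
    seed: int = 0
    algorithm: str = "louvain"
    embedding: str = "pca"  # "pca" (first two PCs) or "umap"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise StimplantError("n_components must be >= 1")
        if self.resolution <= 0:
            raise StimplantError("resolution must be > 0")
        if self.algorithm != "louvain":
            raise StimplantError(f"unsupported algorithm {self.algorithm!r}")


@dataclass
class NormalizedExpression:
    """Log-normalized expression, cells x genes, with zeros preserved."""

    cells: list[str]
    genes: list[str]
    values: np.ndarray  # log1p of size-scaled counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise StimplantError("expression shape mismatch")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def gene_idx(self, genes: Sequence[str]) -> list[int]:
        return [self._gene_index[g] for g in genes]

    def cell_idx(self, cells: Sequence[str]) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cells], dtype=int)

    def delogged(self) -> np.ndarray:
        return np.expm1(self.values)

    def subset_cells(self, cells: Sequence[str]) -> "NormalizedExpression":
        idx = self.cell_idx(cells)
        return NormalizedExpression(
            cells=list(cells), genes=list(self.genes), values=self.values[idx]
        )


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels at one named level.

    Cluster indices are 0..K-1 ordered by decreasing cluster size (ties
    broken by smallest member cell id), so the naming is seed-independent
    given the partition.
    """

    level: str
    labels: pd.Series  # index: cell_id, values: int cluster index
    annotation: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        self.labels.index = self.labels.index.astype(str)

    @property
    def cells(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, cluster: int | str) -> list[str]:
        idx = self.resolve(cluster)
        return list(self.labels.index[self.labels == idx])

    def resolve(self, cluster: int | str) -> int:
        """Map a cluster index or annotation name to the integer index."""
        if isinstance(cluster, (int, np.integer)):
            if int(cluster) not in set(self.labels.unique()):
                raise StimplantError(f"unknown cluster index {cluster}")
            return int(cluster)
        for idx, name in self.annotation.items():
            if name == cluster:
                return idx
        raise StimplantError(f"unknown cluster {cluster!r} at level {self.level!r}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(counts: CountMatrix) -> NormalizedExpression:
    """Scale each cell to the median total count, then log(1 + x).

    Cells with zero total counts are excluded with a warning.
    """
    mat = counts.counts.tocsc()
    totals = np.asarray(mat.sum(axis=0)).ravel()
    if totals.sum() == 0:
        raise StimplantError("count matrix is all zero")
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(counts.cells, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-count cells: {dropped[:5]}"
            + ("..." if len(dropped) > 5 else "")
        )
    mat = mat[:, keep]
    totals = totals[keep]
    target = float(np.median(totals))
    dense = np.asarray(mat.todense(), dtype=float).T  # cells x genes
    scaled = dense * (target / totals)[:, None]
    return NormalizedExpression(
        cells=[c for c, k in zip(counts.cells, keep) if k],
        genes=list(counts.genes),
        values=np.log1p(scaled),
    )


# ---------------------------------------------------------------------------
# Embedding + clustering
# ---------------------------------------------------------------------------


def _pca_space(expr: NormalizedExpression, cfg: ClusteringConfig) -> np.ndarray:
    X = expr.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_comp = min(cfg.n_components, min(Z.shape) - 1) or 1
    if n_comp < cfg.n_components:
        warnings.warn(
            f"reducing n_components from {cfg.n_components} to {n_comp} "
            f"for a {Z.shape[0]}x{Z.shape[1]} matrix"
        )
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=cfg.seed)
    return pca.fit_transform(Z)


def _snn_graph(pcs: np.ndarray, n_neighbors: int, prune: float = 1 / 15) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard weights.

    Edges connect k-nearest neighbors (Euclidean in PC space), weighted by
    the Jaccard overlap of the endpoints' neighbor sets; weights below
    ``prune`` are dropped. This is the construction the standard single-cell
    toolchain feeds to Louvain.
    """
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    nbr = [set(map(int, row)) for row in idx]  # includes self
    g = nx.Graph()
    g.add_nodes_from(range(len(pcs)))
    for i, row in enumerate(idx):
        for j in row[1:]:
            j = int(j)
            if g.has_edge(i, j):
                continue
            inter = len(nbr[i] & nbr[j])
            union = len(nbr[i] | nbr[j])
            w = inter / union
            if w >= prune:
                g.add_edge(i, j, weight=w)
    return g


def _relabel_by_size(
    communities: list[set[int]], cells: list[str]
) -> pd.Series:
    # Order: decreasing size, ties by smallest member cell id.
    ordered = sorted(
        communities, key=lambda c: (-len(c), min(cells[i] for i in c))
    )
    labels = np.empty(len(cells), dtype=int)
    for new_idx, comm in enumerate(ordered):
        for i in comm:
            labels[i] = new_idx
    return pd.Series(labels, index=pd.Index(cells, name="cell_id"))


def embed_and_cluster(
    expr: NormalizedExpression,
    cfg: ClusteringConfig | None = None,
    level: str = "global",
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """PCA -> kNN graph -> Louvain; returns labels and a 2-D embedding.

    The embedding is computed from the same PC space (first two PCs by
    default, UMAP when ``cfg.embedding == "umap"``) and carries no contract
    beyond determinism at a fixed seed.
    """
    cfg = cfg or ClusteringConfig()
    n_cells = len(expr.cells)
    if n_cells < cfg.n_neighbors + 1:
        raise StimplantError(
            f"need at least n_neighbors+1={cfg.n_neighbors + 1} cells, got {n_cells}"
        )
    pcs = _pca_space(expr, cfg)
    graph = _snn_graph(pcs, cfg.n_neighbors)
    communities = nx.community.louvain_communities(
        graph, resolution=cfg.resolution, seed=cfg.seed, weight="weight"
    )
    labels = _relabel_by_size([set(c) for c in communities], expr.cells)
    if cfg.embedding == "umap":
        import umap

        emb = umap.UMAP(
            n_neighbors=cfg.n_neighbors, random_state=cfg.seed
        ).fit_transform(pcs)
    else:
        emb = pcs[:, : min(2, pcs.shape[1])]
        if emb.shape[1] < 2:
            emb = np.column_stack([emb, np.zeros(len(emb))])
    embedding = pd.DataFrame(
        {"cell_id": expr.cells, "dim1": emb[:, 0], "dim2": emb[:, 1]}
    )
    return ClusterAssignment(level=level, labels=labels), embedding


def subcluster(
    expr: NormalizedExpression,
    parent: ClusterAssignment,
    target: int | str,
    cfg: ClusteringConfig | None = None,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Re-cluster the cells of one parent cluster with the same parameters."""
    cfg = cfg or ClusteringConfig()
    idx = parent.resolve(target)
    members = parent.members(idx)
    if len(members) < cfg.n_neighbors + 1:
        raise StimplantError(
            f"cluster {target!r} has {len(members)} cells; need >= "
            f"{cfg.n_neighbors + 1} to subcluster"
        )
    sub_expr = expr.subset_cells(members)
    name = parent.annotation.get(idx, str(idx))
    return embed_and_cluster(sub_expr, cfg, level=f"{parent.level}/{name}")


# ---------------------------------------------------------------------------
# Statistics helpers
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def _group_stats(
    expr: NormalizedExpression,
    in_idx: np.ndarray,
    out_idx: np.ndarray,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    vals = expr.values
    in_vals = vals[in_idx]
    out_vals = vals[out_idx]
    pct_in = (in_vals > 0).mean(axis=0)
    pct_out = (out_vals > 0).mean(axis=0)
    mean_in = np.expm1(in_vals).mean(axis=0)
    mean_out = np.expm1(out_vals).mean(axis=0)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    if test == "wilcoxon":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                in_vals, out_vals, axis=0, alternative="two-sided"
            )
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "t":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(in_vals, out_vals, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise StimplantError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "log2fc": log2fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p_value": p,
            "p_adj": bh_adjust(p),
        }
    )


# ---------------------------------------------------------------------------
# Markers and differential expression
# ---------------------------------------------------------------------------


def find_markers(
    expr: NormalizedExpression,
    assignment: ClusterAssignment,
    cluster: int | str,
    min_pct: float = 0.5,
    min_log2fc: float = 0.25,
    test: str = "wilcoxon",
    return_all: bool = False,
) -> pd.DataFrame:
    """Marker genes of one cluster vs all other cells.

    Retains genes with ``pct_in >= min_pct`` and ``log2fc > min_log2fc``;
    p-values from a two-sided Wilcoxon rank-sum test on normalized values,
    BH-adjusted across all tested genes.
    """
    idx = assignment.resolve(cluster)
    members = assignment.members(idx)
    others = [c for c in assignment.cells if assignment.labels[c] != idx]
    if len(members) < 3:
        raise StimplantError(
            f"cluster {cluster!r} has {len(members)} cells; rank test needs >= 3"
        )
    if not others:
        raise StimplantError(f"cluster {cluster!r} covers all cells")
    table = _group_stats(expr, expr.cell_idx(members), expr.cell_idx(others), test)
    table.insert(0, "cluster", idx)
    if not return_all:
        table = table[(table["pct_in"] >= min_pct) & (table["log2fc"] > min_log2fc)]
    return table.sort_values(
        ["log2fc", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def volcano_flag(
    log2fc,
    neglog10_p,
    fc_threshold: float = 1.0,
    neglog10p_threshold: float = 2.0,
):
    """Significance rule: log2fc >= fc AND -log10 p >= threshold, inclusive."""
    return (np.asarray(log2fc) >= fc_threshold) & (
        np.asarray(neglog10_p) >= neglog10p_threshold
    )


def differential_expression(
    expr: NormalizedExpression,
    sample_of: pd.Series,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    fc_threshold: float = 1.0,
    neglog10p_threshold: float = 2.0,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene differential expression between two condition groups.

    ``sample_of`` maps cell_id -> sample_id. Genes are flagged significant
    when log2fc >= fc_threshold and -log10(p) >= neglog10p_threshold (both
    inclusive, raw p); the BH-adjusted p is reported alongside. Output is
    sorted by log2fc descending.
    """
    set_a, set_b = set(samples_a), set(samples_b)
    if set_a & set_b:
        raise StimplantError(f"overlapping sample sets: {sorted(set_a & set_b)}")
    sample_of = sample_of.astype(str)
    sample_of.index = sample_of.index.astype(str)
    cells_a = [c for c in expr.cells if sample_of.get(c) in set_a]
    cells_b = [c for c in expr.cells if sample_of.get(c) in set_b]
    if not cells_a or not cells_b:
        raise StimplantError("both groups must contain cells")
    # Convention: group b (e.g. implant) vs group a (e.g. skin), so positive
    # log2fc means higher in group b.
    table = _group_stats(expr, expr.cell_idx(cells_b), expr.cell_idx(cells_a), test)
    table = table.rename(columns={"pct_in": "pct_b", "pct_out": "pct_a"})
    table["neglog10_p"] = -np.log10(np.maximum(table["p_value"], 1e-300))
    table["significant"] = volcano_flag(
        table["log2fc"], table["neglog10_p"], fc_threshold, neglog10p_threshold
    )
    return table.sort_values(
        ["log2fc", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cluster frequencies
# ---------------------------------------------------------------------------


def cluster_frequencies(
    assignment: ClusterAssignment, sample_of: pd.Series
) -> pd.DataFrame:
    """Per-sample per-cluster cell counts and fractions.

    Clusters absent from a sample get an explicit zero row; per sample the
    frequencies sum to 1.
    """
    sample_of = sample_of.astype(str)
    sample_of.index = sample_of.index.astype(str)
    missing = [c for c in assignment.cells if c not in sample_of.index]
    if missing:
        raise StimplantError(
            f"{len(missing)} cells have no sample mapping: {missing[:5]}"
        )
    df = pd.DataFrame(
        {
            "cell_id": assignment.cells,
            "cluster": assignment.labels.values,
            "sample_id": [sample_of[c] for c in assignment.cells],
        }
    )
    clusters = sorted(df["cluster"].unique())
    rows = []
    for sid, grp in df.groupby("sample_id", sort=True):
        n_total = len(grp)
        counts = grp["cluster"].value_counts()
        for k in clusters:
            n = int(counts.get(k, 0))
            rows.append(
                {
                    "sample_id": sid,
                    "level": assignment.level,
                    "cluster": k,
                    "n_cells": n,
                    "frequency": n / n_total,
                }
            )
    return pd.DataFrame(rows)


def compare_frequencies(
    freqs: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    group_a_name: str = "a",
    group_b_name: str = "b",
) -> tuple[pd.DataFrame, list[int]]:
    """Student's t per cluster on per-sample frequencies.

    Returns the full comparison table plus the list of clusters that are
    significantly more frequent in group b (raw p < alpha and
    mean_b > mean_a) — the gate used for colocalization inclusion.
    """
    set_a, set_b = [str(s) for s in group_a], [str(s) for s in group_b]
    if len(set_a) < 2 or len(set_b) < 2:
        raise StimplantError("need >= 2 samples per group")
    rows = []
    comparisons: list[GroupComparison] = []
    for k in sorted(freqs["cluster"].unique()):
        sub = freqs[freqs["cluster"] == k].set_index("sample_id")["frequency"]
        va = [float(sub.get(s, 0.0)) for s in set_a]
        vb = [float(sub.get(s, 0.0)) for s in set_b]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = compare_values(
                va, vb, metric=f"frequency_cluster_{k}",
                group_a=group_a_name, group_b=group_b_name,
            )
        comparisons.append(cmp)
        rows.append({"cluster": k, **cmp.to_dict()})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched_in_b"] = (table["p_value"] < alpha) & (
        table["mean_b"] > table["mean_a"]
    )
    flagged = [int(k) for k in table.loc[table["enriched_in_b"], "cluster"]]
    return table, flagged


# ---------------------------------------------------------------------------
# Gene-program scoring
# ---------------------------------------------------------------------------


def program_score(
    expr: NormalizedExpression, gene_panel: Sequence[str]
) -> pd.Series:
    """Per-cell mean normalized expression over the panel genes present."""
    panel = list(dict.fromkeys(gene_panel))
    present = [g for g in panel if g in expr.genes]
    missing = [g for g in panel if g not in expr.genes]
    if not present:
        raise StimplantError("no panel genes present in the expression matrix")
    if missing:
        warnings.warn(f"panel genes missing from matrix: {missing}")
    idx = expr.gene_idx(present)
    scores = expr.values[:, idx].mean(axis=1)
    return pd.Series(scores, index=pd.Index(expr.cells, name="cell_id"), name="score")
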