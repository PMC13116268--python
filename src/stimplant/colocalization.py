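"""Radius-neighborhood colocalization between subclusters.

Around every cell of a source subcluster a closed disc of fixed radius
(default 25 µm) is drawn and the cells of each target subcluster inside it
are counted (distance <= radius, boundary inclusive; a cell is never its
own neighbor). Totals are pair-symmetric for distinct subclusters; the
diagonal counts each within-cluster pair twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from stimplant.io_formats import StimplantError


@dataclass
class ColocalizationMatrix:
    """Directed neighbor-count matrices between subclusters at one radius."""

    level: str
    radius: float
    subclusters: list
    total_counts: np.ndarray  # (K, K) ints, source row -> target column
    mean_per_cell: np.ndarray  # total / source cluster size
    n_source_cells: np.ndarray  # (K,) ints

    def __post_init__(self) -> None:
        self.total_counts = np.asarray(self.total_counts)
        k = len(self.subclusters)
        if self.total_counts.shape != (k, k):
            raise StimplantError("total_counts shape mismatch")

    def total_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.total_counts, index=self.subclusters, columns=self.subclusters
        )

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_per_cell, index=self.subclusters, columns=self.subclusters
        )


def neighbor_counts(
    source_cells: np.ndarray,
    target_cells: np.ndarray,
    radius: float,
    exclude_self: bool = False,
) -> tuple[np.ndarray, int]:
    """Count target cells within ``radius`` (inclusive) of each source cell.

    ``exclude_self=True`` declares that source and target are the same cell
    list, so each cell's own entry is excluded from its count.
    """
    if radius <= 0:
        raise StimplantError(f"radius must be > 0, got {radius}")
    src = np.asarray(source_cells, dtype=float)
    tgt = np.asarray(target_cells, dtype=float)
    if len(src) == 0 or len(tgt) == 0:
        return np.zeros(len(src), dtype=int), 0
    tree = cKDTree(tgt)
    counts = np.asarray(
        tree.query_ball_point(src, r=radius, return_length=True), dtype=int
    )
    if exclude_self:
        if src.shape != tgt.shape or not np.array_equal(src, tgt):
            raise StimplantError(
                "exclude_self requires identical source and target lists"
            )
        counts = counts - 1
    return counts, int(counts.sum())


def colocalization_matrix(
    cells: pd.DataFrame,
    assignment,
    included_subclusters: Sequence[int] | None = None,
    radius: float = 25.0,
) -> ColocalizationMatrix:
    """Pairwise neighbor-count matrix over the included subclusters.

    ``cells`` must contain cell_id, x, y for every cell in the assignment.
    When ``included_subclusters`` is None, all subclusters are included —
    the intended gating is the significantly-enriched set returned by
    ``compare_frequencies``.
    """
    if radius <= 0:
        raise StimplantError(f"radius must be > 0, got {radius}")
    if included_subclusters is None:
        included = list(range(assignment.n_clusters))
    else:
        included = list(included_subclusters)
    if not included:
        raise StimplantError("included_subclusters is empty")
    known = set(assignment.labels.unique())
    unknown = [k for k in included if k not in known]
    if unknown:
        raise StimplantError(f"unknown subcluster labels: {unknown}")

    pos = cells.copy()
    pos["cell_id"] = pos["cell_id"].astype(str)
    pos = pos.set_index("cell_id")
    points: dict[int, np.ndarray] = {}
    for k in included:
        members = assignment.members(k)
        missing = [c for c in members if c not in pos.index]
        if missing:
            raise StimplantError(
                f"cells missing coordinates: {missing[:5]}"
            )
        points[k] = pos.loc[members, ["x", "y"]].to_numpy(float)

    n_k = len(included)
    total = np.zeros((n_k, n_k), dtype=int)
    trees = {k: cKDTree(points[k]) for k in included if len(points[k])}
    for i, a in enumerate(included):
        if len(points[a]) == 0:
            continue
        for j, b in enumerate(included):
            if b not in trees:
                continue
            counts = np.asarray(
                trees[b].query_ball_point(points[a], r=radius, return_length=True),
                dtype=int,
            )
            if a == b:
                counts = counts - 1
            total[i, j] = int(counts.sum())
    n_source = np.array([len(points[k]) for k in included], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(n_source[:, None] > 0, total / np.maximum(n_source[:, None], 1), 0.0)
    return ColocalizationMatrix(
        level=assignment.level,
        radius=float(radius),
        subclusters=included,
        total_counts=total,
        mean_per_cell=mean,
        n_source_cells=n_source,
    )


def export_interaction(
    matrix: ColocalizationMatrix, use: str = "total"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chord-ready edge list (upper triangle + diagonal) and full heatmap.

    Edges carry total counts by default (``use="mean"`` switches to the
    per-source-cell means); zero-weight edges are retained.
    """
    if use == "total":
        mat = matrix.total_counts
    elif use == "mean":
        mat = matrix.mean_per_cell
    else:
        raise StimplantError(f"unknown weight kind {use!r}")
    labels = matrix.subclusters
    rows = []
    for i in range(len(labels)):
        for j in range(i, len(labels)):
            rows.append(
                {"source": labels[i], "target": labels[j], "weight": mat[i, j]}
            )
    edges = pd.DataFrame(rows)
    heatmap = pd.DataFrame(mat, index=labels, columns=labels)
    heatmap.index.name = "subcluster"
    return edges, heatmap


def edges_to_matrix(edges: pd.DataFrame, subclusters: Sequence) -> np.ndarray:
    """Rebuild a symmetric matrix from an upper-triangle edge list."""
    labels = list(subclusters)
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for _, row in edges.iterrows():
        i, j = idx[row["source"]], idx[row["target"]]
        mat[i, j] = row["weight"]
        mat[j, i] = row["weight"]
    return mat
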