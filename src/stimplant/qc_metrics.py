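"""Dataset quality-control metrics and between-group comparisons.

Metrics cover the transcript quality mixture at a Phred-like threshold,
transcript-to-cell assignment rates, and transcript/cell spatial densities.
Group comparisons use the equal-variance two-sample Student's t-test with
mean +/- SEM summaries; Welch's correction is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from stimplant.io_formats import SpatialSample, StimplantError, UNASSIGNED

DEFAULT_QV_THRESHOLD = 20.0

UM2_PER_MM2 = 1e6


@dataclass
class QCReport:
    """Per-sample quality-control metrics."""

    sample_id: str
    n_transcripts: int
    n_cells: int
    frac_high_quality: float
    frac_low_quality: float
    frac_transcripts_in_cells: float
    frac_cells_no_transcripts: float
    transcripts_per_um2: float
    cells_per_mm2: float
    area_um2: float
    qv_threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupComparison:
    """Two-group summary for one metric: means, SEMs, fold change, t, p."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_area_um2(sample: SpatialSample) -> float:
    """Tissue area: the ROI polygon if given, else the cell-centroid hull."""
    if sample.tissue_roi is not None:
        return sample.tissue_roi.polygon().area
    pts = sample.cells[["x", "y"]].to_numpy(float)
    if len(pts) < 3:
        raise StimplantError(
            "no tissue_roi and fewer than 3 cells: cannot determine area"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise StimplantError(
            "no tissue_roi and cell centroids are degenerate (collinear): "
            "cannot determine area"
        ) from exc
    return float(hull.volume)  # 2-D: 'volume' is the area


def compute_qc(
    sample: SpatialSample, qv_threshold: float = DEFAULT_QV_THRESHOLD
) -> QCReport:
    """Compute the QC report for one sample.

    ``frac_high_quality`` counts transcripts with qv >= threshold;
    densities are normalized by the tissue ROI area when annotated and by
    the convex hull of cell centroids otherwise.
    """
    tx = sample.transcripts
    cells = sample.cells
    if len(tx) == 0:
        raise StimplantError(f"sample {sample.sample_id!r} has no transcripts")
    if len(cells) == 0:
        raise StimplantError(f"sample {sample.sample_id!r} has no cells")

    n_tx = len(tx)
    frac_high = float((tx["qv"] >= qv_threshold).sum() / n_tx)
    assigned = tx["cell_id"] != UNASSIGNED
    frac_in_cells = float(assigned.sum() / n_tx)
    cells_with_tx = set(tx.loc[assigned, "cell_id"])
    frac_empty = float(sum(c not in cells_with_tx for c in cells["cell_id"]) / len(cells))
    area = _sample_area_um2(sample)
    return QCReport(
        sample_id=sample.sample_id,
        n_transcripts=n_tx,
        n_cells=len(cells),
        frac_high_quality=frac_high,
        frac_low_quality=1.0 - frac_high,
        frac_transcripts_in_cells=frac_in_cells,
        frac_cells_no_transcripts=frac_empty,
        transcripts_per_um2=n_tx / area,
        cells_per_mm2=len(cells) / area * UM2_PER_MM2,
        area_um2=area,
        qv_threshold=float(qv_threshold),
    )


def qc_table(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def compare_values(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "value",
    group_a: str = "a",
    group_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test on raw per-sample values.

    Equal-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption. Zero variance in both groups with equal
    means yields t = 0, p = 1 (with a warning) rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StimplantError(
            f"need >= 2 values per group, got {len(a)} and {len(b)}"
        )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(a.std(ddof=1) / np.sqrt(len(a)))
    sem_b = float(b.std(ddof=1) / np.sqrt(len(b)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn(
            f"metric {metric!r}: zero variance in both groups; reporting "
            "t=0, p=1 by convention"
        )
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(b, a, equal_var=not welch)
        t_stat, p_val = float(t_stat), float(p_val)
        if np.isnan(t_stat):
            warnings.warn(f"metric {metric!r}: degenerate t-test; p=1 by convention")
            t_stat, p_val = 0.0, 1.0
    fold = mean_b / mean_a if mean_a > 0 else float("nan")
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        fold_change=fold,
        t_statistic=t_stat,
        p_value=p_val,
        n_a=len(a),
        n_b=len(b),
    )


def compare_metric(
    reports_a: Sequence[QCReport],
    reports_b: Sequence[QCReport],
    metric: str,
    group_a: str = "a",
    group_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Compare one QC metric between two groups of per-sample reports."""
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise StimplantError("need >= 2 reports per group")
    va = [getattr(r, metric) for r in reports_a]
    vb = [getattr(r, metric) for r in reports_b]
    return compare_values(va, vb, metric=metric, group_a=group_a, group_b=group_b, welch=welch)
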