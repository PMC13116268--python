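"""Signed distance to the implant surface and three-region localization.

Distance magnitude is the minimum Euclidean (point-to-segment) distance to
the boundary; the sign is negative inside the polygon (even-odd rule) and
exactly zero on the boundary. Regions: ``scaffold_body`` (d < 0),
``capsule`` (outside, within the capsule band), ``skin`` (beyond). Points
exactly on the surface (d = 0) belong to the capsule, not the body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from stimplant.io_formats import BoundaryAnnotation, GeometryError, StimplantError

REGIONS = ("scaffold_body", "capsule", "skin")


@dataclass
class RegionConfig:
    """How the capsule/skin division is drawn outside the scaffold.

    ``outer_boundary`` uses a manually annotated outer capsule polygon;
    ``fixed_thickness`` (default, 100 µm) draws a fixed-width band and
    needs no extra annotation.
    """

    capsule_mode: str = "fixed_thickness"
    capsule_thickness: float = 100.0

    def __post_init__(self) -> None:
        if self.capsule_mode not in ("outer_boundary", "fixed_thickness"):
            raise StimplantError(f"unknown capsule_mode {self.capsule_mode!r}")
        if self.capsule_mode == "fixed_thickness" and self.capsule_thickness <= 0:
            raise StimplantError("capsule_thickness must be > 0")


def _as_components(
    boundary: BoundaryAnnotation | Sequence[BoundaryAnnotation],
) -> list[BoundaryAnnotation]:
    if isinstance(boundary, BoundaryAnnotation):
        return [boundary]
    comps = list(boundary)
    if not comps:
        raise GeometryError("no boundary components given")
    return comps


def signed_distances(
    points: np.ndarray,
    boundary: BoundaryAnnotation | Sequence[BoundaryAnnotation],
) -> np.ndarray:
    """Vectorized signed distance of (n, 2) points to a (multi-)boundary.

    Magnitude is the distance to the nearest component's edge; the sign is
    negative iff the point lies strictly inside any component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise StimplantError(f"points must be (n, 2), got {pts.shape}")
    comps = _as_components(boundary)
    for c in comps:
        if not c.closed:
            raise GeometryError(f"boundary {c.name!r} must be closed")
    geoms = shapely.points(pts)
    dist = np.full(len(pts), np.inf)
    inside = np.zeros(len(pts), dtype=bool)
    for c in comps:
        poly = c.polygon()
        ring = poly.exterior
        dist = np.minimum(dist, shapely.distance(geoms, ring))
        inside |= shapely.contains(poly, geoms)
    return np.where(inside, -dist, dist)


def signed_distance(
    point: tuple[float, float],
    boundary: BoundaryAnnotation | Sequence[BoundaryAnnotation],
) -> float:
    """Signed distance of one point; see :func:`signed_distances`."""
    return float(signed_distances(np.asarray([point], dtype=float), boundary)[0])


def assign_regions(
    cells: pd.DataFrame,
    scaffold: BoundaryAnnotation | Sequence[BoundaryAnnotation],
    cfg: RegionConfig | None = None,
    capsule_outer: BoundaryAnnotation | None = None,
) -> pd.DataFrame:
    """Per-cell signed distance and region assignment.

    Returns a table with ``cell_id``, ``distance`` (µm, signed), ``region``.
    """
    cfg = cfg or RegionConfig()
    if cfg.capsule_mode == "outer_boundary":
        if capsule_outer is None:
            raise StimplantError(
                "capsule_mode='outer_boundary' requires a capsule_outer boundary"
            )
        outer_poly = capsule_outer.polygon()
        for comp in _as_components(scaffold):
            vertices = shapely.points(comp.vertices)
            if not shapely.covers(outer_poly, vertices).all():
                raise GeometryError(
                    f"capsule_outer {capsule_outer.name!r} does not enclose "
                    f"scaffold component {comp.name!r}"
                )
    pts = cells[["x", "y"]].to_numpy(float)
    d = signed_distances(pts, scaffold)
    region = np.full(len(d), "skin", dtype=object)
    region[d < 0] = "scaffold_body"
    outside = d >= 0
    if cfg.capsule_mode == "fixed_thickness":
        region[outside & (d <= cfg.capsule_thickness)] = "capsule"
    else:
        in_outer = shapely.covers(capsule_outer.polygon(), shapely.points(pts))
        region[outside & in_outer] = "capsule"
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].astype(str).to_numpy(),
            "distance": d,
            "region": region,
        }
    )


def subcluster_region(
    distance_table: pd.DataFrame,
    assignment,
    level: str | None = None,
) -> pd.DataFrame:
    """Per-subcluster region label plus distance summary stats.

    The subcluster label is the majority region of its cells; ties are
    broken by the region of the median-distance cell. Output columns:
    cluster, region, n_cells, median_distance, q1, q3.
    """
    level = level or assignment.level
    dist = distance_table.set_index("cell_id")
    missing = [c for c in assignment.cells if c not in dist.index]
    if missing:
        raise StimplantError(
            f"{len(missing)} cells missing from distance table: {missing[:5]}"
        )
    rows = []
    for k in range(assignment.n_clusters):
        members = assignment.members(k)
        if not members:
            raise StimplantError(f"subcluster {k} is empty")
        sub = dist.loc[members]
        counts = sub["region"].value_counts()
        top = counts.max()
        tied = sorted(counts[counts == top].index)
        if len(tied) == 1:
            label = tied[0]
        else:
            med = sub["distance"].median()
            # region of the cell whose distance is closest to the median
            label = sub.iloc[(sub["distance"] - med).abs().argmin()]["region"]
        rows.append(
            {
                "level": level,
                "cluster": k,
                "region": label,
                "n_cells": len(sub),
                "median_distance": float(sub["distance"].median()),
                "q1": float(sub["distance"].quantile(0.25)),
                "q3": float(sub["distance"].quantile(0.75)),
            }
        )
    return pd.DataFrame(rows)


def distance_profiles(
    distance_table: pd.DataFrame, assignment
) -> pd.DataFrame:
    """Long-format per-cell distances with cluster labels (violin-ready)."""
    dist = distance_table.set_index("cell_id")
    rows = []
    for cell in assignment.cells:
        rows.append(
            {
                "cell_id": cell,
                "cluster": int(assignment.labels[cell]),
                "distance": float(dist.loc[cell, "distance"]),
                "region": dist.loc[cell, "region"],
            }
        )
    return pd.DataFrame(rows)
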