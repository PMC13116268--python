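"""Synthetic in-situ datasets with known ground truth.

Generates sections that mimic an implanted-scaffold experiment: a scaffold
polygon with a capsule band and surrounding skin, region-specific cell
densities (homogeneous Poisson per region) and cluster compositions,
negative-binomial counts with planted marker fold-changes, per-cell
log-normal library factors, and a high/low transcript-quality mixture.
Control ("skin") sections have no scaffold and uniform skin density.

Everything is driven by one study seed; per-sample seeds are spawned
deterministically so identical configs yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import Polygon, box

from stimplant.io_formats import (
    BoundaryAnnotation,
    CountMatrix,
    SpatialSample,
    StimplantError,
    UNASSIGNED,
    write_boundary,
    write_count_matrix,
    write_table,
)

DEFAULT_CLUSTERS = (
    "keratinocyte",
    "fibroblast",
    "macrophage",
    "neutrophil",
    "endothelial",
)


@dataclass
class MarkerSpec:
    """Planted marker block: ``n_genes`` genes up in ``cluster``."""

    cluster: int
    n_genes: int
    log2fc: float
    pct_expressing: float


@dataclass
class SimulationConfig:
    field_size: tuple[float, float] = (1000.0, 1000.0)  # µm
    scaffold_ellipse: tuple[float, float, float, float] = (500.0, 500.0, 250.0, 160.0)
    scaffold_vertices: int = 64
    capsule_thickness: float = 100.0
    # cells per mm^2 by region; "skin" also sets control-section density
    densities: dict = field(
        default_factory=lambda: {
            "scaffold_body": 900.0,
            "capsule": 1500.0,
            "skin": 600.0,
        }
    )
    cluster_names: tuple = DEFAULT_CLUSTERS
    cluster_composition: dict = field(
        default_factory=lambda: {
            "skin": [0.45, 0.30, 0.10, 0.01, 0.14],
            "capsule": [0.10, 0.35, 0.30, 0.10, 0.15],
            "scaffold_body": [0.05, 0.25, 0.40, 0.20, 0.10],
        }
    )
    # optional control-section overrides; None falls back to the "skin"
    # entries above (which otherwise describe the skin *region* of
    # implanted sections)
    control_density: float | None = None
    control_composition: list | None = None
    n_genes: int = 100
    markers: list = field(
        default_factory=lambda: [
            MarkerSpec(cluster=k, n_genes=6, log2fc=2.0, pct_expressing=0.8)
            for k in range(5)
        ]
    )
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.3  # expected counts/gene/cell for non-markers
    marker_baseline_mean: float = 1.0  # out-of-cluster mean for marker genes
    libsize_sigma: float = 0.2
    qv_high_frac: float = 0.852
    qv_high_range: tuple[float, float] = (20.0, 40.0)
    qv_low_range: tuple[float, float] = (0.0, 20.0)
    unassigned_frac: float = 0.05  # extra extracellular transcripts
    transcript_scatter: float = 10.0  # µm around the centroid
    n_samples_per_condition: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for region, probs in self.cluster_composition.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise StimplantError(
                    f"cluster composition for {region!r} does not sum to 1"
                )
            if len(probs) != len(self.cluster_names):
                raise StimplantError(
                    f"composition for {region!r} has {len(probs)} entries for "
                    f"{len(self.cluster_names)} clusters"
                )
        if any(d < 0 for d in self.densities.values()):
            raise StimplantError("densities must be >= 0")
        if self.control_composition is not None:
            if abs(sum(self.control_composition) - 1.0) > 1e-9:
                raise StimplantError("control_composition does not sum to 1")
            if len(self.control_composition) != len(self.cluster_names):
                raise StimplantError("control_composition length mismatch")
        if self.control_density is not None and self.control_density < 0:
            raise StimplantError("control_density must be >= 0")
        if not 0 <= self.qv_high_frac <= 1:
            raise StimplantError("qv_high_frac must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise StimplantError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """Row-for-row truth for an emitted sample."""

    sample_id: str
    condition: str
    cells: pd.DataFrame  # cell_id, region, cluster (int), cluster_name
    genes: pd.DataFrame  # gene, marker_cluster (-1 = null), log2fc, pct_expressing
    region_areas_um2: dict
    config: SimulationConfig


def _scaffold_polygon(cfg: SimulationConfig) -> np.ndarray:
    cx, cy, a, b = cfg.scaffold_ellipse
    t = np.linspace(0, 2 * np.pi, cfg.scaffold_vertices, endpoint=False)
    return np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])


def _gene_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Assign marker blocks to the leading genes; the rest are nulls."""
    n_marker = sum(m.n_genes for m in cfg.markers)
    if n_marker > cfg.n_genes:
        raise StimplantError(
            f"{n_marker} marker genes exceed n_genes={cfg.n_genes}"
        )
    width = max(3, len(str(cfg.n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    marker_cluster = np.full(cfg.n_genes, -1, dtype=int)
    log2fc = np.zeros(cfg.n_genes)
    pct = np.zeros(cfg.n_genes)
    pos = 0
    for m in cfg.markers:
        marker_cluster[pos : pos + m.n_genes] = m.cluster
        log2fc[pos : pos + m.n_genes] = m.log2fc
        pct[pos : pos + m.n_genes] = m.pct_expressing
        pos += m.n_genes
    return pd.DataFrame(
        {
            "gene": genes,
            "marker_cluster": marker_cluster,
            "log2fc": log2fc,
            "pct_expressing": pct,
        }
    )


def _sample_points_in_regions(
    cfg: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Poisson point placement per region; returns (points, regions, areas)."""
    w, h = cfg.field_size
    field_poly = box(0, 0, w, h)
    if condition == "skin":
        area = field_poly.area
        density = (
            cfg.control_density
            if cfg.control_density is not None
            else cfg.densities["skin"]
        )
        n = rng.poisson(density * area / 1e6)
        pts = rng.uniform([0, 0], [w, h], size=(n, 2))
        return pts, np.full(n, "skin", dtype=object), {"skin": area}

    scaffold = Polygon(_scaffold_polygon(cfg))
    if not field_poly.covers(scaffold):
        raise StimplantError("scaffold exceeds the field")
    capsule = scaffold.buffer(cfg.capsule_thickness).intersection(field_poly).difference(
        scaffold
    )
    skin = field_poly.difference(scaffold.buffer(cfg.capsule_thickness))
    areas = {
        "scaffold_body": scaffold.area,
        "capsule": capsule.area,
        "skin": skin.area,
    }
    region_polys = {"scaffold_body": scaffold, "capsule": capsule, "skin": skin}
    all_pts, all_regions = [], []
    import shapely

    for region, poly in region_polys.items():
        lam = cfg.densities[region] * areas[region] / 1e6
        n = int(rng.poisson(lam))
        got: list[np.ndarray] = []
        n_got = 0
        minx, miny, maxx, maxy = poly.bounds
        frac = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)
        while n_got < n:
            batch = max(int((n - n_got) / frac * 1.3), 32)
            cand = rng.uniform([minx, miny], [maxx, maxy], size=(batch, 2))
            keep = shapely.covers(poly, shapely.points(cand))
            sel = cand[keep][: n - n_got]
            got.append(sel)
            n_got += len(sel)
        pts = np.vstack(got) if got else np.empty((0, 2))
        all_pts.append(pts)
        all_regions.append(np.full(len(pts), region, dtype=object))
    return np.vstack(all_pts), np.concatenate(all_regions), areas


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial: var = m + m^2/dispersion."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        lam = rng.gamma(shape=dispersion, scale=mean[pos] / dispersion)
        out[pos] = rng.poisson(lam)
    return out


def simulate_sample(
    cfg: SimulationConfig,
    condition: str,
    seed: int | None = None,
    sample_id: str | None = None,
) -> tuple[SpatialSample, GroundTruth]:
    """Generate one section of the given condition ("skin" or "PCL")."""
    if condition not in ("skin", "PCL"):
        raise StimplantError(f"condition must be 'skin' or 'PCL', got {condition!r}")
    seed = cfg.seed if seed is None else seed
    sample_id = sample_id or f"{condition}_{seed}"
    rng = np.random.default_rng(seed)

    pts, regions, areas = _sample_points_in_regions(cfg, condition, rng)
    n_cells = len(pts)
    if n_cells == 0:
        raise StimplantError("simulation produced zero cells; raise densities")
    width = max(4, len(str(n_cells - 1)))
    cell_ids = [f"{sample_id}_c{i:0{width}d}" for i in range(n_cells)]
    cell_areas = rng.lognormal(mean=np.log(100.0), sigma=0.3, size=n_cells)

    # cluster per cell from the region's composition
    gene_truth = _gene_truth(cfg)
    n_clusters = len(cfg.cluster_names)
    clusters = np.empty(n_cells, dtype=int)
    for region in np.unique(regions):
        mask = regions == region
        if condition == "skin" and cfg.control_composition is not None:
            probs = np.asarray(cfg.control_composition, dtype=float)
        else:
            probs = np.asarray(cfg.cluster_composition[region], dtype=float)
        clusters[mask] = rng.choice(n_clusters, size=mask.sum(), p=probs)

    # per-gene per-cell NB means
    is_marker = gene_truth["marker_cluster"].to_numpy() >= 0
    base = np.where(is_marker, cfg.marker_baseline_mean, cfg.baseline_mean)
    means = np.tile(base[:, None], (1, n_cells)).astype(float)  # genes x cells
    for gi in np.flatnonzero(is_marker):
        k = int(gene_truth.loc[gi, "marker_cluster"])
        fc = 2.0 ** float(gene_truth.loc[gi, "log2fc"])
        pct = float(gene_truth.loc[gi, "pct_expressing"])
        in_cluster = clusters == k
        expressing = in_cluster & (rng.uniform(size=n_cells) < pct)
        means[gi, expressing] *= fc
    lib = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n_cells)
    means *= lib[None, :]
    counts = _nb_draw(rng, means, cfg.nb_dispersion)
    count_matrix = CountMatrix(
        genes=list(gene_truth["gene"]),
        cells=cell_ids,
        counts=sp.csr_matrix(counts),
    )

    transcripts = _expand_transcripts(cfg, rng, counts, pts, cell_ids, gene_truth)

    w, h = cfg.field_size
    roi = BoundaryAnnotation(
        name="tissue_roi",
        vertices=np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float),
    )
    boundaries = []
    if condition == "PCL":
        boundaries.append(
            BoundaryAnnotation(name="scaffold", vertices=_scaffold_polygon(cfg))
        )
    cells_df = pd.DataFrame(
        {"cell_id": cell_ids, "x": pts[:, 0], "y": pts[:, 1], "area": cell_areas}
    )
    sample = SpatialSample(
        sample_id=sample_id,
        condition=condition,
        transcripts=transcripts,
        cells=cells_df,
        counts=count_matrix,
        boundaries=boundaries,
        tissue_roi=roi,
    )
    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "region": regions,
            "cluster": clusters,
            "cluster_name": [cfg.cluster_names[k] for k in clusters],
        }
    ).sort_values("cell_id", kind="stable").reset_index(drop=True)
    truth = GroundTruth(
        sample_id=sample_id,
        condition=condition,
        cells=truth_cells,
        genes=gene_truth,
        region_areas_um2=areas,
        config=cfg,
    )
    return sample, truth


def _expand_transcripts(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    counts: np.ndarray,
    centroids: np.ndarray,
    cell_ids: list[str],
    gene_truth: pd.DataFrame,
) -> pd.DataFrame:
    gi, ci = np.nonzero(counts)
    reps = counts[gi, ci]
    gene_idx = np.repeat(gi, reps)
    cell_idx = np.repeat(ci, reps)
    n_assigned = len(gene_idx)
    # uniform scatter in a disc around the parent centroid
    r = cfg.transcript_scatter * np.sqrt(rng.uniform(size=n_assigned))
    theta = rng.uniform(0, 2 * np.pi, size=n_assigned)
    xy = centroids[cell_idx] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    genes = gene_truth["gene"].to_numpy()[gene_idx]
    owners = np.asarray(cell_ids, dtype=object)[cell_idx]

    n_extra = int(rng.poisson(cfg.unassigned_frac * n_assigned))
    w, h = cfg.field_size
    xy_extra = rng.uniform([0, 0], [w, h], size=(n_extra, 2))
    genes_extra = gene_truth["gene"].to_numpy()[
        rng.integers(0, len(gene_truth), size=n_extra)
    ]
    xs = np.concatenate([xy[:, 0], xy_extra[:, 0]])
    ys = np.concatenate([xy[:, 1], xy_extra[:, 1]])
    all_genes = np.concatenate([genes, genes_extra])
    all_owners = np.concatenate(
        [owners, np.full(n_extra, UNASSIGNED, dtype=object)]
    )
    n_total = n_assigned + n_extra
    high = rng.uniform(size=n_total) < cfg.qv_high_frac
    qv = np.where(
        high,
        rng.uniform(*cfg.qv_high_range, size=n_total),
        rng.uniform(*cfg.qv_low_range, size=n_total),
    )
    width = max(6, len(str(max(n_total - 1, 1))))
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i:0{width}d}" for i in range(n_total)],
            "gene": all_genes,
            "x": xs,
            "y": ys,
            "qv": qv,
            "cell_id": all_owners,
        }
    )


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[list[tuple[SpatialSample, GroundTruth]], pd.DataFrame]:
    """Simulate n sections per condition with deterministic per-sample seeds."""
    if cfg.n_samples_per_condition < 1:
        raise StimplantError("n_samples_per_condition must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(
        2 * cfg.n_samples_per_condition
    )]
    out = []
    rows = []
    i = 0
    for condition in ("skin", "PCL"):
        for rep in range(cfg.n_samples_per_condition):
            sid = f"{condition}_{rep + 1}"
            sample, truth = simulate_sample(
                cfg, condition, seed=child_seeds[i], sample_id=sid
            )
            out.append((sample, truth))
            rows.append({"sample_id": sid, "condition": condition})
            i += 1
    return out, pd.DataFrame(rows)


def write_sample(sample: SpatialSample, out_dir: str | Path) -> dict[str, str]:
    """Write one sample in the CSV/MTX/GeoJSON dialects the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": str(out / "transcripts.csv"),
        "cells": str(out / "cells.csv"),
        "matrix": str(out / "matrix.mtx"),
        "genes": str(out / "genes.txt"),
        "matrix_cells": str(out / "matrix_cells.txt"),
    }
    write_table(sample.transcripts, paths["transcripts"])
    write_table(sample.cells, paths["cells"])
    write_count_matrix(
        sample.counts, paths["matrix"], paths["genes"], paths["matrix_cells"]
    )
    if sample.tissue_roi is not None:
        paths["tissue_roi"] = str(out / "tissue_roi.geojson")
        write_boundary(sample.tissue_roi, paths["tissue_roi"])
    bmap = {}
    for b in sample.boundaries:
        p = str(out / f"boundary_{b.name}.geojson")
        write_boundary(b, p)
        bmap[b.name] = p
    if bmap:
        paths["boundaries"] = bmap
    return paths


def write_study(
    cfg: SimulationConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, list[tuple[SpatialSample, GroundTruth]]]:
    """Simulate and write a study; returns the manifest (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, manifest = simulate_study(cfg)
    rows = []
    for sample, truth in pairs:
        sdir = out / sample.sample_id
        paths = write_sample(sample, sdir)
        write_table(truth.cells, sdir / "truth_cells.csv")
        write_table(truth.genes, sdir / "truth_genes.csv")
        row = {
            "sample_id": sample.sample_id,
            "condition": sample.condition,
            "transcripts": paths["transcripts"],
            "cells": paths["cells"],
            "matrix": paths["matrix"],
            "genes": paths["genes"],
            "matrix_cells": paths["matrix_cells"],
            "tissue_roi": paths.get("tissue_roi", ""),
            "scaffold": paths.get("boundaries", {}).get("scaffold", ""),
        }
        rows.append(row)
    manifest_full = pd.DataFrame(rows)
    write_table(manifest_full, out / "manifest.csv")
    _write_marker_gmt(pairs[0][1], out / "marker_sets.gmt")
    return manifest_full, pairs


def _write_marker_gmt(truth: GroundTruth, path: Path) -> None:
    """Emit the planted marker blocks as a GMT for annotation/enrichment."""
    from stimplant.enrichment import GeneSetCollection
    from stimplant.io_formats import write_gene_sets

    names = truth.config.cluster_names
    sets = {}
    for k, name in enumerate(names):
        genes = list(
            truth.genes.loc[truth.genes["marker_cluster"] == k, "gene"]
        )
        if genes:
            sets[f"{name}_signature"] = genes
    write_gene_sets(GeneSetCollection(sets=sets), path)
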