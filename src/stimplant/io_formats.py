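"""Readers, writers, and validated in-memory types for all on-disk artifacts.

Coordinates are micrometres throughout, origin arbitrary, y increasing
upward. Polygons are stored without a repeated closing vertex and are
normalized to counter-clockwise orientation on load. Extracellular
transcripts carry the sentinel cell id ``"unassigned"`` rather than a null.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon

UNASSIGNED = "unassigned"

TRANSCRIPT_COLUMNS = ["transcript_id", "gene", "x", "y", "qv", "cell_id"]
CELL_COLUMNS = ["cell_id", "x", "y", "area"]


class StimplantError(ValueError):
    """Base class for validation failures."""


class SchemaError(StimplantError):
    """A required column or field is missing or malformed."""


class ReferentialError(StimplantError):
    """A record references an identifier that does not exist."""


class GeometryError(StimplantError):
    """A boundary polygon violates a geometric invariant."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class BoundaryAnnotation:
    """A named closed (or open) polyline in µm coordinates.

    ``vertices`` is an (n, 2) float array; for closed boundaries the first
    vertex is not repeated at the end (closure is implicit).
    """

    name: str
    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError(
                f"boundary {self.name!r}: vertices must be (n, 2), got shape "
                f"{self.vertices.shape}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError(f"boundary {self.name!r}: non-finite vertex coordinates")
        if self.closed:
            # Drop an explicit closing vertex if present.
            if len(self.vertices) >= 2 and np.allclose(
                self.vertices[0], self.vertices[-1]
            ):
                self.vertices = self.vertices[:-1]
            if len(self.vertices) < 3:
                raise GeometryError(
                    f"boundary {self.name!r}: closed boundary needs >= 3 vertices, "
                    f"got {len(self.vertices)}"
                )
            poly = Polygon(self.vertices)
            if not poly.is_valid or poly.area <= 0:
                raise GeometryError(
                    f"boundary {self.name!r}: polygon is self-intersecting or degenerate"
                )
            if _signed_area(self.vertices) < 0:
                self.vertices = self.vertices[::-1].copy()

    def polygon(self) -> Polygon:
        if not self.closed:
            raise GeometryError(f"boundary {self.name!r} is not closed")
        return Polygon(self.vertices)


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer counts."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise SchemaError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise SchemaError("count matrix contains negative values")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise SchemaError("count matrix contains non-integer values")
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError("duplicate gene names in count matrix")
        if len(set(self.cells)) != len(self.cells):
            raise SchemaError("duplicate cell ids in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


# ---------------------------------------------------------------------------
# Sample
# ---------------------------------------------------------------------------


@dataclass
class SpatialSample:
    """One tissue section: transcripts + cells + counts + boundaries."""

    sample_id: str
    condition: str
    transcripts: pd.DataFrame
    cells: pd.DataFrame
    counts: CountMatrix
    boundaries: list[BoundaryAnnotation] = field(default_factory=list)
    tissue_roi: BoundaryAnnotation | None = None

    def __post_init__(self) -> None:
        self.transcripts = _validate_transcripts(self.transcripts)
        self.cells = _validate_cells(self.cells)
        known = set(self.cells["cell_id"])
        refs = set(self.transcripts["cell_id"]) - {UNASSIGNED}
        orphans = sorted(refs - known)
        if orphans:
            raise ReferentialError(
                f"transcripts reference unknown cell ids: {orphans[:10]}"
                + ("..." if len(orphans) > 10 else "")
            )
        extra = sorted(set(self.counts.cells) - known)
        if extra:
            raise ReferentialError(
                f"count matrix references unknown cell ids: {extra[:10]}"
            )

    def boundary(self, name: str) -> BoundaryAnnotation:
        for b in self.boundaries:
            if b.name == name:
                return b
        raise KeyError(f"sample {self.sample_id!r} has no boundary named {name!r}")


def _validate_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"transcript table missing columns: {missing}")
    df = df[TRANSCRIPT_COLUMNS].copy()
    df["transcript_id"] = df["transcript_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    df["cell_id"] = df["cell_id"].astype(str)
    for col in ("x", "y", "qv"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy())):
        raise SchemaError("transcript coordinates must be finite")
    if (df["qv"] < 0).any():
        raise SchemaError("transcript qv must be >= 0")
    return df.reset_index(drop=True)


def _validate_cells(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    df = df[CELL_COLUMNS].copy()
    df["cell_id"] = df["cell_id"].astype(str)
    for col in ("x", "y", "area"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if df["cell_id"].duplicated().any():
        dupes = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique())
        raise SchemaError(f"duplicate cell ids: {dupes[:10]}")
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy())):
        raise SchemaError("cell coordinates must be finite")
    if (df["area"] < 0).any():
        raise SchemaError("cell area must be >= 0")
    # Canonical row order: cells sorted by id.
    return df.sort_values("cell_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_boundary(path: str | Path, name: str | None = None, closed: bool = True) -> BoundaryAnnotation:
    """Read one boundary from a GeoJSON Polygon or a CSV vertex list."""
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        return _read_geojson_boundary(path, name)
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"boundary CSV {path} missing column {col!r}")
    return BoundaryAnnotation(
        name=name or path.stem, vertices=df[["x", "y"]].to_numpy(float), closed=closed
    )


def _read_geojson_boundary(path: Path, name: str | None) -> BoundaryAnnotation:
    obj = json.loads(path.read_text())
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if len(feats) != 1:
            raise SchemaError(
                f"{path}: expected exactly one feature, found {len(feats)}"
            )
        obj = feats[0]
    props = {}
    if obj.get("type") == "Feature":
        props = obj.get("properties") or {}
        obj = obj.get("geometry") or {}
    if obj.get("type") != "Polygon":
        raise SchemaError(f"{path}: expected GeoJSON Polygon, got {obj.get('type')!r}")
    rings = obj.get("coordinates", [])
    if not rings:
        raise GeometryError(f"{path}: Polygon has no rings")
    if len(rings) > 1:
        raise GeometryError(f"{path}: Polygon with holes is not supported")
    return BoundaryAnnotation(
        name=name or props.get("name", path.stem),
        vertices=np.asarray(rings[0], dtype=float),
        closed=True,
    )


def write_boundary(boundary: BoundaryAnnotation, path: str | Path) -> None:
    """Write a closed boundary as a GeoJSON Polygon feature."""
    ring = boundary.vertices.tolist()
    ring.append(ring[0])
    obj = {
        "type": "Feature",
        "properties": {"name": boundary.name},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }
    Path(path).write_text(json.dumps(obj))


def read_count_matrix(
    matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> CountMatrix:
    """Read an MTX triplet file with gene/cell name sidecars."""
    mat = scipy.io.mmread(str(matrix_path))
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(mat))


def write_count_matrix(
    cm: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.counts), field="integer")
    Path(genes_path).write_text("\n".join(cm.genes) + ("\n" if cm.genes else ""))
    Path(cells_path).write_text("\n".join(cm.cells) + ("\n" if cm.cells else ""))


def read_sample(
    paths: Mapping[str, object],
    sample_id: str,
    condition: str,
) -> SpatialSample:
    """Assemble and validate a :class:`SpatialSample` from on-disk artifacts.

    Parameters
    ----------
    paths
        Mapping with keys ``transcripts``, ``cells``, ``matrix``, ``genes``,
        ``matrix_cells`` (file paths), optionally ``tissue_roi`` (path) and
        ``boundaries`` (mapping of boundary name -> path, or list of paths).
    """
    required = ["transcripts", "cells", "matrix", "genes", "matrix_cells"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise SchemaError(f"read_sample: missing path entries {missing}")
    transcripts = pd.read_csv(paths["transcripts"])
    cells = pd.read_csv(paths["cells"])
    counts = read_count_matrix(paths["matrix"], paths["genes"], paths["matrix_cells"])
    boundaries: list[BoundaryAnnotation] = []
    bspec = paths.get("boundaries")
    if isinstance(bspec, Mapping):
        boundaries = [read_boundary(p, name=n) for n, p in bspec.items()]
    elif isinstance(bspec, Sequence) and not isinstance(bspec, (str, bytes)):
        boundaries = [read_boundary(p) for p in bspec]
    elif bspec is not None:
        boundaries = [read_boundary(bspec)]
    roi = None
    if paths.get("tissue_roi"):
        roi = read_boundary(paths["tissue_roi"], name="tissue_roi")
    return SpatialSample(
        sample_id=sample_id,
        condition=condition,
        transcripts=transcripts,
        cells=cells,
        counts=counts,
        boundaries=boundaries,
        tissue_roi=roi,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result as UTF-8 CSV with header and '.' decimals.

    NaN serializes as an empty field; row order is preserved as given
    (callers are responsible for a deterministic ordering).
    """
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_gene_sets(path: str | Path):
    """Read a GMT file (name TAB description TAB gene...) into a collection.

    Duplicate genes within a set are removed (first occurrence kept);
    duplicate set names are an error. An empty file yields an empty
    collection.
    """
    from stimplant.enrichment import GeneSetCollection

    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise SchemaError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if len(genes) < len([g for g in fields[2:] if g]):
                warnings.warn(f"GMT set {name!r}: duplicated genes removed")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
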