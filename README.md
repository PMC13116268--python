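# stimplant

Single-cell spatial transcriptomics analysis for tissue sections containing
implanted biomaterials. The package covers the full workflow for a
two-condition (control skin vs. implanted) study design:

- **QC** (`stimplant.qc_metrics`) — transcript quality mixture at a
  Phred-like threshold, transcript-to-cell assignment rates, transcript/cell
  spatial densities, and equal-variance Student's t comparisons between
  condition groups (mean ± SEM, fold change).
- **Clustering** (`stimplant.clustering`) — median-library-size
  normalization + log1p, PCA (15 components), Jaccard-weighted
  shared-nearest-neighbor graph, Louvain at resolution 0.8, subclustering
  with the same parameters, Wilcoxon marker detection with expression-
  fraction (≥50%) and log2FC (>0.25) cutoffs, volcano-style differential
  expression (log2FC ≥ 1, −log10 p ≥ 2), cluster frequency statistics, and
  gene-program scoring.
- **Spatial localization** (`stimplant.spatial_metrics`) — signed
  perpendicular distance of every cell to the scaffold surface (negative =
  inside), three-region assignment (scaffold body / capsule / skin) with
  either an annotated outer capsule boundary or a fixed-thickness band, and
  per-subcluster region summaries.
- **Colocalization** (`stimplant.colocalization`) — directed
  neighbor-count matrices between subclusters within a 25 µm radius
  (closed disc), with chord-ready edge-list and heatmap exports.
- **Enrichment** (`stimplant.enrichment`) — one-sided hypergeometric
  over-representation against user-supplied GMT gene sets, with BH
  adjustment and cluster annotation.
- **Synthetic data** (`stimplant.synthetic_data`) — a generator for
  Xenium-like sections with known ground truth: region-structured cell
  densities, per-region cluster compositions, negative-binomial counts with
  planted marker fold changes, and a high/low transcript-quality mixture.
- **IO** (`stimplant.io_formats`) — validated readers/writers for the CSV /
  MTX / GeoJSON / GMT dialects used throughout.

## CLI

```sh
# generate a synthetic two-condition study with ground truth
stimplant simulate --out study/ --seed 0 --samples-per-condition 4

# individual stages
stimplant qc --samples study/manifest.csv --out qc.csv
stimplant cluster --samples study/manifest.csv --out clusters.csv \
    --embedding-out embedding.csv
stimplant distance --sample-dir study/PCL_1 \
    --boundary study/PCL_1/boundary_scaffold.geojson --out distances.csv
stimplant coloc --cells study/PCL_1/cells.csv --clusters clusters.csv \
    --radius 25 --out coloc
stimplant enrich --genes markers.csv --gmt study/marker_sets.gmt --out enr.csv

# everything at once
stimplant run --manifest study/manifest.csv --gmt study/marker_sets.gmt \
    --out results/
```

`run` writes the full bundle (QC + comparison, clusters, embedding,
markers, DE, frequencies + comparison, distances, regions, colocalization
matrix/edges, enrichment, annotations) as CSV plus a `run_metadata.json`
provenance record; reruns with the same config are bit-identical.

The manifest is a CSV with columns `sample_id, condition, transcripts,
cells, matrix, genes, matrix_cells` and optionally `tissue_roi, scaffold`
(file paths). `simulate` writes a ready-to-use study in exactly this
layout.

## Conventions

- Coordinates are micrometres; y increases upward; polygons are stored
  counter-clockwise without a repeated closing vertex.
- Extracellular transcripts carry the cell id sentinel `"unassigned"`.
- Signed distance is negative strictly inside the scaffold; cells exactly
  on the surface (d = 0) belong to the capsule.
- Neighbor counting uses a closed disc (distance ≤ radius) and never counts
  a cell as its own neighbor.
- The default capsule is a fixed 100 µm band outside the scaffold surface;
  pass an annotated outer boundary to reproduce manual capsule delineation.
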