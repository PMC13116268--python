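import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stimplant.io_formats import (
    BoundaryAnnotation,
    CountMatrix,
    SpatialSample,
)
from stimplant.synthetic_data import SimulationConfig, simulate_study


def make_tiny_sample(sample_id="s1", condition="skin"):
    """3 cells, 10 transcripts, hand-written."""
    cells = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "x": [10.0, 50.0, 90.0],
            "y": [10.0, 50.0, 90.0],
            "area": [100.0, 120.0, 80.0],
        }
    )
    transcripts = pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(10)],
            "gene": ["gA", "gA", "gB", "gB", "gA", "gC", "gC", "gA", "gB", "gC"],
            "x": [10.0, 11, 50, 51, 90, 91, 10, 50, 90, 30],
            "y": [10.0, 11, 50, 51, 90, 91, 12, 52, 88, 30],
            "qv": [25.0, 30, 15, 35, 22, 18, 40, 21, 19, 33],
            "cell_id": ["c1", "c1", "c2", "c2", "c3", "c3", "c1", "c2", "c3",
                        "unassigned"],
        }
    )
    counts = CountMatrix(
        genes=["gA", "gB", "gC"],
        cells=["c1", "c2", "c3"],
        counts=sp.csr_matrix(
            np.array([[2, 1, 1], [0, 2, 1], [1, 1, 1]], dtype=int)
        ),
    )
    roi = BoundaryAnnotation(
        "tissue_roi", np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]])
    )
    return SpatialSample(
        sample_id=sample_id,
        condition=condition,
        transcripts=transcripts,
        cells=cells,
        counts=counts,
        tissue_roi=roi,
    )


@pytest.fixture
def tiny_sample():
    return make_tiny_sample()


@pytest.fixture
def unit_square():
    return BoundaryAnnotation(
        "square", np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
    )


@pytest.fixture(scope="session")
def small_study():
    """One deterministic small study shared across tests."""
    cfg = SimulationConfig(
        field_size=(600.0, 600.0),
        scaffold_ellipse=(300.0, 300.0, 150.0, 100.0),
        capsule_thickness=80.0,
        densities={"scaffold_body": 1200.0, "capsule": 1800.0, "skin": 800.0},
        n_samples_per_condition=2,
        seed=42,
    )
    pairs, manifest = simulate_study(cfg)
    return cfg, pairs, manifest
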