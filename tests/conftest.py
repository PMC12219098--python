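import numpy as np
import pandas as pd
import pytest

from spatialtme import DEFAULT_VOCABULARY, CellMap


def make_cellmap(points, sample_id="S1", roi_id="R1", group="A", vocabulary=DEFAULT_VOCABULARY):
    """CellMap from a list of (cell_id, x, y, phenotype) tuples."""
    cells = pd.DataFrame(points, columns=["cell_id", "x_um", "y_um", "phenotype"])
    return CellMap(sample_id=sample_id, roi_id=roi_id, group=group, cells=cells,
                   vocabulary=vocabulary)


@pytest.fixture
def random_roi():
    """A ~200-cell random ROI with all core phenotypes present."""
    from spatialtme import csr_cellmap

    return csr_cellmap(
        200,
        phenotypes=["Tumor", "Fibroblast", "C1QC_RTM", "CD4_T", "CD8_T", "B", "Other"],
        probs=[0.4, 0.15, 0.12, 0.12, 0.08, 0.05, 0.08],
        seed=42,
        width=500.0,
        height=500.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One R/NR cohort (2 samples x 2 ROIs per group) shared across tests."""
    from spatialtme import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=2), master_seed=7)
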