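"""Container invariants, CSV round-trips and cell frequencies."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    DEFAULT_VOCABULARY,
    CellMap,
    PhenotypeVocabulary,
    SimulationConfig,
    cell_frequencies,
    generate_cohort,
    read_cell_table,
    read_marker_table,
    write_cell_table,
    write_marker_table,
)
from spatialtme.data import SchemaError, ValidationError, arcsinh_normalize, to_anndata

from conftest import make_cellmap


def test_read_toy_file_single_roi(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text(
        "sample_id,roi_id,group,cell_id,x_um,y_um,phenotype\n"
        "S1,R1,MSS_R,c1,0.0,0.0,Tumor\n"
        "S1,R1,MSS_R,c2,10.0,0.0,CD4_T\n"
        "S1,R1,MSS_R,c3,0.0,10.0,Fibroblast\n"
    )
    maps = read_cell_table(p)
    assert len(maps) == 1
    cm = maps[0]
    assert cm.key == ("S1", "R1") and cm.group == "MSS_R" and cm.n_cells == 3
    assert list(cm.cell_ids) == ["c1", "c2", "c3"]


def test_missing_column_names_the_column(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text("sample_id,roi_id,group,cell_id,x_um,phenotype\nS1,R1,A,c1,0,Tumor\n")
    with pytest.raises(SchemaError, match="y_um"):
        read_cell_table(p)


def test_duplicate_cell_id_rejected(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text(
        "sample_id,roi_id,group,cell_id,x_um,y_um,phenotype\n"
        "S1,R1,A,c1,0,0,Tumor\nS1,R1,A,c1,1,1,Tumor\n"
    )
    with pytest.raises(ValidationError, match="c1"):
        read_cell_table(p)


def test_unknown_phenotype_rejected_unless_mapped(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text(
        "sample_id,roi_id,group,cell_id,x_um,y_um,phenotype\n"
        "S1,R1,A,c1,0,0,Weird\nS1,R1,A,c2,1,1,Tumor\n"
    )
    with pytest.raises(ValidationError, match="Weird"):
        read_cell_table(p)
    maps = read_cell_table(p, other_label="Other")
    assert list(maps[0].phenotypes) == ["Other", "Tumor"]


def test_write_read_write_round_trip_is_byte_identical(tmp_path):
    cohort = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=1), master_seed=3)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cell_table(cohort.cellmaps, p1)
    write_cell_table(read_cell_table(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_marker_round_trip_and_alignment(tmp_path):
    cohort = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=1), master_seed=3)
    p = tmp_path / "markers.csv"
    write_marker_table(cohort.markers, p)
    markers = read_marker_table(p, cohort.cellmaps)
    cm = cohort.cellmaps[0]
    got = markers[cm.key]
    assert list(got.index) == list(cm.cell_ids)
    np.testing.assert_allclose(got.to_numpy(), cohort.markers[cm.key].to_numpy(), rtol=1e-12)


def test_vocabulary_role_validation():
    with pytest.raises(ValidationError):
        PhenotypeVocabulary(names=("A", "B"), barrier_source="C")
    with pytest.raises(ValidationError):
        PhenotypeVocabulary(names=("A", "B"), barrier_source="A", barrier_target="A")
    with pytest.raises(ValidationError):
        PhenotypeVocabulary(names=("A", "A"))
    vocab = PhenotypeVocabulary(names=("A",))
    with pytest.raises(ValidationError):
        vocab.require_barrier_roles()


def test_cells_outside_declared_bounds_rejected():
    cells = pd.DataFrame(
        {"cell_id": ["c1"], "x_um": [50.0], "y_um": [5.0], "phenotype": ["Tumor"]}
    )
    with pytest.raises(ValidationError, match="bounds"):
        CellMap("S", "R", "A", cells, bounds=(0, 0, 10, 10))


@pytest.mark.parametrize(
    "points,expected",
    [
        ([(f"c{i}", float(i), 0.0, "Tumor") for i in range(10)], {"Tumor": 1.0}),
        (
            [(f"c{i}", float(i), 0.0, "Tumor") for i in range(4)]
            + [(f"d{i}", float(i), 5.0, "CD4_T") for i in range(6)],
            {"Tumor": 0.4, "CD4_T": 0.6},
        ),
    ],
)
def test_cell_frequencies(points, expected):
    freq = cell_frequencies(make_cellmap(points))
    for pheno in DEFAULT_VOCABULARY.names:
        assert freq[pheno] == pytest.approx(expected.get(pheno, 0.0))
    assert freq.sum() == pytest.approx(1.0, abs=1e-12)


def test_frequencies_sum_to_one_across_cohort(small_cohort):
    for cm in small_cohort.cellmaps:
        assert abs(cell_frequencies(cm).sum() - 1.0) < 1e-12


def test_arcsinh_convenience():
    df = pd.DataFrame({"a": [0.0, 5.0]})
    out = arcsinh_normalize(df, cofactor=5.0)
    assert out["a"].iloc[0] == 0.0
    assert out["a"].iloc[1] == pytest.approx(np.arcsinh(1.0))
    with pytest.raises(ValidationError):
        arcsinh_normalize(df, cofactor=0)


def test_anndata_export(small_cohort):
    adata = to_anndata(small_cohort.cellmaps[:2], small_cohort.markers)
    assert adata.n_obs == sum(cm.n_cells for cm in small_cohort.cellmaps[:2])
    assert adata.obsm["spatial"].shape == (adata.n_obs, 2)
    assert "phenotype" in adata.obs
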