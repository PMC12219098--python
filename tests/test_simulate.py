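"""Synthetic-cohort generator: determinism, CSR behavior, planted effects."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    GroupSpec,
    SimulationConfig,
    generate_cohort,
    generate_roi,
    nn_distances,
)

from oracles import clark_evans_z


def test_same_seed_reproduces_roi_exactly():
    cfg = SimulationConfig.rnr_preset(n_samples_per_group=1)
    cm1, mk1, gt1 = generate_roi(cfg, "NR", seed=11)
    cm2, mk2, gt2 = generate_roi(cfg, "NR", seed=11)
    pd.testing.assert_frame_equal(cm1.cells, cm2.cells)
    pd.testing.assert_frame_equal(mk1, mk2)
    assert gt1 == gt2


def test_cells_inside_bounds_and_markers_aligned():
    cfg = SimulationConfig.rnr_preset(n_samples_per_group=1)
    cm, mk, _ = generate_roi(cfg, "R", seed=2)
    x0, y0, x1, y1 = cm.bounds
    xy = cm.coords
    assert (xy[:, 0] >= x0).all() and (xy[:, 0] <= x1).all()
    assert (xy[:, 1] >= y0).all() and (xy[:, 1] <= y1).all()
    assert list(mk.index) == list(cm.cell_ids)
    assert not mk.isna().to_numpy().any()


def test_zero_intensity_config_rejected():
    cfg = SimulationConfig.homogeneous_preset()
    cfg.background_density = {k: 0.0 for k in cfg.background_density}
    with pytest.raises(ValueError, match="intensity"):
        generate_roi(cfg, "A", seed=0)


def test_unknown_group_rejected():
    with pytest.raises(ValueError, match="unknown group"):
        generate_roi(SimulationConfig.rnr_preset(), "pCR", seed=0)


def test_homogeneous_config_passes_csr_check():
    """With clustering and barriers off, each phenotype is indistinguishable
    from complete spatial randomness (Clark-Evans, Donnelly-corrected)."""
    cfg = SimulationConfig.homogeneous_preset()
    n_tests = n_pass = 0
    for seed in range(50):
        cm, _, _ = generate_roi(cfg, "A", seed=seed)
        for pheno in ("Tumor", "C1QC_RTM", "CD4_T"):
            pts = cm.coords[cm.phenotypes == pheno]
            if len(pts) < 10:
                continue
            n_tests += 1
            if abs(clark_evans_z(pts, 1000.0, 1000.0)) < 1.96:
                n_pass += 1
    assert n_pass / n_tests >= 0.9


def test_clustered_types_fail_csr_check():
    """The planted Thomas clusters are real aggregation, not noise."""
    cfg = SimulationConfig.rnr_preset(n_samples_per_group=1)
    rejected = 0
    for seed in range(10):
        cm, _, _ = generate_roi(cfg, "NR", seed=seed)
        pts = cm.coords[cm.phenotypes == "C1QC_RTM"]
        if clark_evans_z(pts, 1000.0, 1000.0) < -1.96:  # aggregation side
            rejected += 1
    assert rejected >= 9


def test_activation_boost_elevates_proximal_cd4_markers():
    cfg = SimulationConfig.rnr_preset(n_samples_per_group=1)
    for seed in range(20):
        cm, mk, gt = generate_roi(cfg, "R", seed=seed)
        boosted = gt["activation_boosted_ids"]
        cd4 = set(cm.cell_ids[cm.phenotypes == "CD4_T"])
        distal = sorted(cd4 - set(boosted))
        assert len(boosted) >= 20 and len(distal) >= 20
        assert mk.loc[boosted, "GZMB"].mean() > mk.loc[distal, "GZMB"].mean()


def test_background_counts_are_poisson_consistent():
    cfg = SimulationConfig.homogeneous_preset()
    counts = []
    for seed in range(100):
        cm, _, _ = generate_roi(cfg, "A", seed=seed)
        counts.append(int((cm.phenotypes == "B").sum()))
    counts = np.asarray(counts, dtype=float)
    ratio = counts.var(ddof=1) / counts.mean()
    assert 0.7 <= ratio <= 1.3


def test_cohort_layout_matches_study_design():
    cohort = generate_cohort(SimulationConfig(), master_seed=0)
    assert len(cohort.cellmaps) == 50  # 25 samples x 2 ROIs
    groups = cohort.groups()
    assert groups.value_counts().to_dict() == {
        "MSS_NR": 16, "MSS_R": 16, "MSI_R": 10, "MSI_NR": 8,
    }


def test_restricted_group_set():
    cohort = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=1), master_seed=0)
    assert set(cohort.groups()) == {"R", "NR"}


def test_master_seeds_give_disjoint_roi_streams():
    c1 = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=2), master_seed=0)
    c2 = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=2), master_seed=1)
    states1 = {tuple(gt["seed_state"]) for gt in c1.ground_truth.values()}
    states2 = {tuple(gt["seed_state"]) for gt in c2.ground_truth.values()}
    assert len(states1) == len(c1.ground_truth)  # distinct within a cohort
    assert states1.isdisjoint(states2)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig.rnr_preset(n_samples_per_group=3)
    cfg.group_marker_mu_shift = {"R": {"GZMB": 0.3}}
    p = tmp_path / "config.yaml"
    cfg.to_yaml(p)
    cfg2 = SimulationConfig.from_yaml(p)
    assert cfg2 == cfg


def test_group_spec_validation():
    with pytest.raises(ValueError):
        GroupSpec(n_samples=0, p_share=0.5, p_barrier=0.5)
    with pytest.raises(ValueError):
        GroupSpec(n_samples=1, p_share=1.5, p_barrier=0.5)


def test_cohort_write_emits_text_artifacts(tmp_path):
    cohort = generate_cohort(SimulationConfig.rnr_preset(n_samples_per_group=1), master_seed=0)
    cohort.write(tmp_path)
    assert (tmp_path / "cells.csv").exists()
    assert (tmp_path / "markers.csv").exists()
    assert (tmp_path / "ground_truth.json").exists()
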