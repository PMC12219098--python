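"""Fibroblast barrier score: worked example, invariants, oracle equivalence."""

import numpy as np
import pytest

from spatialtme import (
    GroupSpec,
    SimulationConfig,
    barrier_scores,
    build_knn_graph,
    generate_roi,
    rtm_adjacent_fibroblasts,
)

from conftest import make_cellmap
from oracles import brute_barrier_per_cell


def schematic_roi(interm_phenos=("Fibroblast", "Fibroblast", "Fibroblast", "Other")):
    """One CD4 cell with four equidistant arms, each leading to an RTM.

    Each arm has an intermediate cell at 10 μm and an RTM at 20 μm, so all
    four RTMs tie at graph distance 20; pad cells around each RTM keep the
    direct CD4-RTM link out of the 4-NN graph, making [CD4, intermediate,
    RTM] the unique shortest path per arm. The intermediates on three arms
    are fibroblasts (each sharing an edge with its RTM), so three of the four
    tied-nearest paths are blocked.
    """
    dirs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    pts = [("q_cd4", 0.0, 0.0, "CD4_T")]
    for a, ((ux, uy), pheno) in enumerate(zip(dirs, interm_phenos)):
        vx, vy = -uy, ux
        pts.append((f"m{a}_interm", 10.0 * ux, 10.0 * uy, pheno))
        pts.append((f"t{a}_rtm", 20.0 * ux, 20.0 * uy, "C1QC_RTM"))
        pts.append((f"p{a}_out", 25.0 * ux, 25.0 * uy, "Tumor"))
        pts.append((f"p{a}_left", 20.0 * ux + 5.0 * vx, 20.0 * uy + 5.0 * vy, "Tumor"))
        pts.append((f"p{a}_right", 20.0 * ux - 5.0 * vx, 20.0 * uy - 5.0 * vy, "Tumor"))
    return make_cellmap(pts)


def test_schematic_three_of_four_blocked_paths_score_three_quarters():
    cm = schematic_roi()
    res = barrier_scores(cm, k=4)
    per_cell = res.per_cell.set_index("cell_id")
    assert per_cell.loc["q_cd4", "n_tied_targets"] == 4
    assert per_cell.loc["q_cd4", "score"] == 0.75
    assert res.image_score == 0.75


def test_all_paths_blocked_scores_one():
    cm = schematic_roi(("Fibroblast",) * 4)
    assert barrier_scores(cm, k=4).image_score == 1.0


def test_no_fibroblasts_scores_zero():
    cm = schematic_roi(("Other",) * 4)
    res = barrier_scores(cm, k=4)
    assert res.image_score == 0.0
    assert res.adjacent_fibroblasts == frozenset()


def test_relabel_fibroblasts_to_other_zeroes_score():
    cm = schematic_roi()
    cells = cm.cells.copy()
    cells.loc[cells["phenotype"] == "Fibroblast", "phenotype"] = "Other"
    cm2 = make_cellmap(list(cells.itertuples(index=False)))
    assert barrier_scores(cm2, k=4).image_score == 0.0


def test_adding_adjacent_fibroblast_on_a_path_is_monotone():
    base = barrier_scores(schematic_roi(), k=4).image_score
    more = barrier_scores(schematic_roi(("Fibroblast",) * 4), k=4).image_score
    assert more >= base


def test_count_mode_counts_fibroblasts_along_paths():
    res = barrier_scores(schematic_roi(), k=4, mode="count")
    # one RTM-adjacent fibroblast on each of three paths, none on the fourth
    assert res.image_score == pytest.approx(3 / 4)


def test_missing_roles_reported_not_scored():
    cm = make_cellmap([("c1", 0.0, 0.0, "CD4_T"), ("c2", 5.0, 0.0, "Tumor")])
    res = barrier_scores(cm, k=1)
    assert np.isnan(res.image_score)
    assert "C1QC_RTM" in res.reason


def test_unreachable_query_cells_excluded_and_counted():
    cm = make_cellmap(
        [("a1", 0.0, 0.0, "CD4_T"), ("a2", 1.0, 0.0, "Tumor"),
         ("b1", 1000.0, 0.0, "C1QC_RTM"), ("b2", 1001.0, 0.0, "Tumor")]
    )
    res = barrier_scores(cm, k=1)
    assert res.n_excluded == 1 and res.n_scored == 0
    assert np.isnan(res.image_score)


def test_adjacency_is_one_hop_only():
    # fibroblast f1 shares an edge with the RTM; f2 sits two hops out
    cm = make_cellmap(
        [("r1", 0.0, 0.0, "C1QC_RTM"), ("f1", 5.0, 0.0, "Fibroblast"),
         ("f2", 10.0, 0.0, "Fibroblast"), ("q1", -5.0, 0.0, "CD4_T")]
    )
    g = build_knn_graph(cm, k=1)
    assert rtm_adjacent_fibroblasts(g, cm) == {"f1"}


def test_no_rtm_gives_empty_adjacent_set():
    cm = make_cellmap([("f1", 0.0, 0.0, "Fibroblast"), ("q1", 5.0, 0.0, "CD4_T")])
    g = build_knn_graph(cm, k=1)
    assert rtm_adjacent_fibroblasts(g, cm) == set()


def test_simulated_ring_fibroblasts_are_flagged_adjacent():
    """Rings tight around compact RTM clusters sit within 5-NN reach."""
    cfg = SimulationConfig(
        groups={"NR": GroupSpec(1, 0.15, 1.0)},
        ring_radius=10.0,
        rtm_sigma=5.0,
    )
    flagged = total = 0
    for seed in range(10):
        cm, _, gt = generate_roi(cfg, "NR", seed=seed)
        g = build_knn_graph(cm, k=5)
        adjacent = rtm_adjacent_fibroblasts(g, cm)
        ring_ids = set(gt["ring_fibroblast_ids"])
        flagged += len(ring_ids & adjacent)
        total += len(ring_ids)
    assert total > 0
    assert flagged / total >= 0.9


def test_random_roi_matches_exhaustive_path_oracle(random_roi):
    cm = random_roi.subset(np.arange(random_roi.n_cells) < 150)
    res = barrier_scores(cm, k=5)
    graph = build_knn_graph(cm, k=5)
    oracle = brute_barrier_per_cell(cm, graph)
    got = res.per_cell.set_index("cell_id")["score"]
    assert set(got.index) == set(oracle)
    for cid, expected in oracle.items():
        if np.isnan(expected):
            assert np.isnan(got[cid])
        else:
            assert got[cid] == pytest.approx(expected, abs=1e-9)


def test_mode_and_tol_validation(random_roi):
    with pytest.raises(ValueError):
        barrier_scores(random_roi, mode="bogus")
    with pytest.raises(ValueError):
        barrier_scores(random_roi, tie_tol=-1.0)
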