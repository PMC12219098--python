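"""ROI embeddings, cosine similarity and permutation channel importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from sklearn.linear_model import LogisticRegression

from spatialtme import (
    channel_importance,
    cosine_similarity_matrix,
    feature_matrix,
    roi_feature_vector,
)
from spatialtme.simulate import generate_cohort, informative_channel_config
from spatialtme.similarity import FeatureVector, _shuffled_accuracy

from conftest import make_cellmap


def _vector(cm, markers):
    return roi_feature_vector(cm, markers, scheme="channel_summary")


def test_identical_rois_give_identical_vectors(small_cohort):
    cm = small_cohort.cellmaps[0]
    mk = small_cohort.markers[cm.key]
    v1, v2 = _vector(cm, mk), _vector(cm, mk)
    np.testing.assert_array_equal(v1.values, v2.values)
    assert v1.names == v2.names


def test_single_cell_percentiles_collapse():
    cm = make_cellmap([("c1", 0.0, 0.0, "Tumor")])
    mk = pd.DataFrame({"CD4": [3.5]}, index=pd.Index(["c1"], name="cell_id"))
    v = _vector(cm, mk)
    vals = dict(zip(v.names, v.values))
    assert vals["CD4|mean"] == vals["CD4|p10"] == vals["CD4|p50"] == vals["CD4|p90"] == 3.5
    assert vals["CD4|sd"] == 0.0
    assert vals["composition|Tumor"] == 1.0


def test_doubling_intensities_scales_stats_not_composition(small_cohort):
    cm = small_cohort.cellmaps[0]
    mk = small_cohort.markers[cm.key]
    v1, v2 = _vector(cm, mk), _vector(cm, mk * 2.0)
    for name, a, b in zip(v1.names, v1.values, v2.values):
        if name.startswith("composition|"):
            assert a == b
        else:
            assert b == pytest.approx(2.0 * a, rel=1e-12)


def test_unknown_scheme_lists_registered(small_cohort):
    cm = small_cohort.cellmaps[0]
    with pytest.raises(ValueError, match="channel_summary"):
        roi_feature_vector(cm, small_cohort.markers[cm.key], scheme="resnet18")


def _fv(key, values, group="A"):
    return FeatureVector(values=np.asarray(values, dtype=float),
                         names=[f"f|{i}" for i in range(len(values))],
                         scheme="manual", key=("S", key), group=group)


def test_cosine_hand_values():
    res = cosine_similarity_matrix([_fv("a", [1, 1]), _fv("b", [1, 0]), _fv("c", [0, 1], "B")])
    m = res.matrix.to_numpy()
    assert m[0, 0] == 1.0
    assert m[1, 2] == pytest.approx(0.0, abs=1e-12)  # orthogonal
    assert m[0, 1] == pytest.approx(1 / np.sqrt(2))  # printed-formula hand check
    np.testing.assert_array_equal(m, m.T)
    np.testing.assert_array_equal(np.diag(m), 1.0)


def test_zero_norm_vector_names_roi():
    with pytest.raises(ValueError, match="zero"):
        cosine_similarity_matrix([_fv("a", [0, 0]), _fv("b", [1, 0])])


@given(scale=stn.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None)
def test_cosine_invariant_to_positive_rescaling(scale):
    res1 = cosine_similarity_matrix([_fv("a", [1.0, 2.0, 3.0]), _fv("b", [2.0, 0.5, 1.0])])
    res2 = cosine_similarity_matrix([_fv("a", np.array([1.0, 2.0, 3.0]) * scale), _fv("b", [2.0, 0.5, 1.0])])
    np.testing.assert_allclose(res1.matrix.to_numpy(), res2.matrix.to_numpy(), atol=1e-12)


def test_block_means_exclude_diagonal():
    res = cosine_similarity_matrix([_fv("a", [1, 0]), _fv("b", [1, 0.1]), _fv("c", [0, 1], "B")])
    m = res.matrix.to_numpy()
    assert res.block_means.loc["A", "A"] == pytest.approx(m[0, 1])  # not 1.0
    assert res.block_means.loc["A", "B"] == pytest.approx((m[0, 2] + m[1, 2]) / 2)


def test_within_group_similarity_exceeds_between(small_cohort):
    vectors = [
        roi_feature_vector(cm, small_cohort.markers[cm.key]) for cm in small_cohort.cellmaps
    ]
    res = cosine_similarity_matrix(vectors)
    within = (res.block_means.loc["R", "R"] + res.block_means.loc["NR", "NR"]) / 2
    between = res.block_means.loc["R", "NR"]
    assert within >= between


def test_identity_shuffle_contributes_zero_importance():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 4))
    y = (X[:, 0] > 0).astype(int)
    model = LogisticRegression().fit(X, y)
    baseline = float((model.predict(X) == y).mean())
    acc = _shuffled_accuracy(model, X, y, cols=np.array([0]), perm=np.arange(len(X)))
    assert acc == baseline


def test_planted_channel_ranks_first_and_noise_centers_on_zero():
    cfg = informative_channel_config(channel="GZMB", shift=0.8)
    cohort = generate_cohort(cfg, master_seed=5)
    vectors = [roi_feature_vector(cm, cohort.markers[cm.key]) for cm in cohort.cellmaps]
    X, groups = feature_matrix(vectors)
    table = channel_importance(X, groups, seed=5).set_index("channel")
    assert table.index[0] == "GZMB"
    assert table.loc["GZMB", "importance"] > 0
    noise = table.drop(index=["GZMB"])["importance"]
    assert noise.abs().mean() < 0.05


def test_importance_validation(small_cohort):
    vectors = [roi_feature_vector(cm, small_cohort.markers[cm.key]) for cm in small_cohort.cellmaps]
    X, groups = feature_matrix(vectors)
    with pytest.raises(ValueError, match="2 groups"):
        channel_importance(X, pd.Series("A", index=groups.index))
    with pytest.warns(UserWarning, match="reducing folds"):
        channel_importance(X, groups, n_folds=10, n_repeats=1)
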