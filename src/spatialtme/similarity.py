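"""ROI feature vectors, cosine similarity, and shuffle-based channel importance.

Each ROI is embedded as a fixed-length numeric vector by a named, pluggable
scheme; the default ``channel_summary`` scheme concatenates per-channel
summary statistics (mean, sd, 10th/50th/90th percentiles across cells) with
the ROI's phenotype frequencies. Pairwise similarity is plain cosine,
cos(a, b) = a.b / (|a||b|), reported with within-/between-group block means.

Channel importance follows the permutation-importance protocol: a classifier
predicting the clinical group from the ROI vectors is evaluated with
stratified 5-fold cross-validation; each channel's feature block is then
shuffled across held-out ROIs (three independent scrambles) and the drop in
held-out accuracy relative to baseline is that channel's importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data import CellMap, cell_frequencies, validate_marker_matrix

__all__ = [
    "FeatureVector",
    "roi_feature_vector",
    "feature_matrix",
    "SimilarityResult",
    "cosine_similarity_matrix",
    "channel_importance",
    "SCHEMES",
]


@dataclass
class FeatureVector:
    """One ROI's embedding under a named scheme."""

    values: np.ndarray
    names: list[str]  # feature names, "<block>|<stat>"
    scheme: str
    key: tuple[str, str]
    group: str


def _channel_summary(cellmap: CellMap, markers: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    mat = validate_marker_matrix(markers, cellmap)
    X = mat.to_numpy(dtype=float)
    stats = {
        "mean": X.mean(axis=0),
        "sd": X.std(axis=0, ddof=0),
        "p10": np.percentile(X, 10, axis=0),
        "p50": np.percentile(X, 50, axis=0),
        "p90": np.percentile(X, 90, axis=0),
    }
    values, names = [], []
    for j, ch in enumerate(mat.columns):
        for stat, arr in stats.items():
            values.append(arr[j])
            names.append(f"{ch}|{stat}")
    freq = cell_frequencies(cellmap)
    for pheno, f in freq.items():
        values.append(f)
        names.append(f"composition|{pheno}")
    return np.asarray(values, dtype=float), names


#: Registry of embedding schemes; extensible by assignment.
SCHEMES: dict[str, Callable[[CellMap, pd.DataFrame], tuple[np.ndarray, list[str]]]] = {
    "channel_summary": _channel_summary,
}


def roi_feature_vector(
    cellmap: CellMap, markers: pd.DataFrame, scheme: str = "channel_summary"
) -> FeatureVector:
    """Embed one ROI as a feature vector under a registered scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; registered: {sorted(SCHEMES)}")
    values, names = SCHEMES[scheme](cellmap, markers)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite features for ROI {cellmap.key}")
    return FeatureVector(values=values, names=names, scheme=scheme, key=cellmap.key, group=cellmap.group)


def feature_matrix(vectors: Sequence[FeatureVector]) -> tuple[pd.DataFrame, pd.Series]:
    """Stack ROI feature vectors into (ROI x feature frame, group labels)."""
    if not vectors:
        raise ValueError("no feature vectors")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValueError("feature vectors have inconsistent layouts")
    index = pd.MultiIndex.from_tuples([v.key for v in vectors], names=["sample_id", "roi_id"])
    X = pd.DataFrame([v.values for v in vectors], index=index, columns=names)
    groups = pd.Series([v.group for v in vectors], index=index, name="group")
    return X, groups


@dataclass
class SimilarityResult:
    """ROI x ROI cosine similarities and group-block averages."""

    matrix: pd.DataFrame
    block_means: pd.DataFrame  # group x group mean similarity, diagonal excluded
    groups: pd.Series


def cosine_similarity_matrix(
    vectors: Sequence[FeatureVector] | pd.DataFrame,
    groups: pd.Series | None = None,
) -> SimilarityResult:
    """Pairwise cosine similarity with within-/between-group block means.

    The diagonal is exactly 1 and the matrix exactly symmetric; block means
    exclude the diagonal. A zero-norm ROI vector is an error naming the ROI.
    """
    if isinstance(vectors, pd.DataFrame):
        X, idx = vectors.to_numpy(dtype=float), vectors.index
        if groups is None:
            raise ValueError("groups required when passing a feature frame")
        grp = groups.loc[idx]
    else:
        frame, grp = feature_matrix(list(vectors))
        X, idx = frame.to_numpy(dtype=float), frame.index
    if len(X) < 2:
        raise ValueError("cosine similarity needs at least 2 ROIs")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm feature vector for ROI {idx[zero[0]]}")
    S = (X @ X.T) / np.outer(norms, norms)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    mat = pd.DataFrame(S, index=idx, columns=idx)

    glabels = sorted(grp.unique())
    block = pd.DataFrame(index=glabels, columns=glabels, dtype=float)
    garr = grp.to_numpy()
    offdiag = ~np.eye(len(X), dtype=bool)
    for ga in glabels:
        for gb in glabels:
            sel = np.outer(garr == ga, garr == gb) & offdiag
            block.loc[ga, gb] = S[sel].mean() if sel.any() else np.nan
    return SimilarityResult(matrix=mat, block_means=block, groups=grp)


def _block_slices(names: Sequence[str]) -> dict[str, np.ndarray]:
    """Column indices per feature block (the part of the name before '|')."""
    blocks: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        blocks.setdefault(name.split("|", 1)[0], []).append(j)
    return {b: np.asarray(cols) for b, cols in blocks.items()}


def _shuffled_accuracy(model, X_val: np.ndarray, y_val: np.ndarray, cols: np.ndarray, perm: np.ndarray) -> float:
    """Held-out accuracy after permuting one feature block across validation ROIs.

    An identity permutation leaves the features, and hence the accuracy,
    unchanged — that repeat contributes zero importance.
    """
    Xs = X_val.copy()
    Xs[:, cols] = Xs[perm][:, cols]
    return float((model.predict(Xs) == y_val).mean())


def channel_importance(
    features: pd.DataFrame,
    groups: pd.Series,
    n_repeats: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 100.0,
) -> pd.DataFrame:
    """Permutation importance of each channel block for group classification.

    Parameters
    ----------
    features:
        ROI x feature frame whose column names encode blocks as
        ``"<channel>|<stat>"`` (phenotype frequencies form a ``composition``
        block).
    groups:
        Group label per ROI (>= 2 distinct labels required).
    n_repeats:
        Independent random scrambles per channel (3 by default).
    n_folds:
        Stratified cross-validation folds (5 by default; reduced with a
        warning when the smallest group is smaller).
    C:
        Inverse L2 regularization strength of the linear classifier
        (1 / 0.01, mirroring a weight-decay of 0.01).

    Returns
    -------
    DataFrame with one row per block: baseline accuracy, mean shuffled
    accuracy, importance = baseline - shuffled, and rank (1 = most important).
    """
    y = groups.loc[features.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("channel importance needs at least 2 groups")
    min_group = int(pd.Series(y).value_counts().min())
    if min_group < n_folds:
        warnings.warn(
            f"smallest group has {min_group} ROIs < n_folds={n_folds}; reducing folds",
            stacklevel=2,
        )
        n_folds = max(2, min_group)
    X = features.to_numpy(dtype=float)
    blocks = _block_slices(list(features.columns))
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    base_accs = []
    drop_accs: dict[str, list[float]] = {b: [] for b in blocks}
    for train, val in skf.split(X, y):
        model = LogisticRegression(C=C, max_iter=2000)  # L2-penalized by default
        model.fit(X[train], y[train])
        acc = float((model.predict(X[val]) == y[val]).mean())
        base_accs.append(acc)
        for b, cols in blocks.items():
            for _ in range(n_repeats):
                perm = rng.permutation(len(val))
                drop_accs[b].append(_shuffled_accuracy(model, X[val], y[val], cols, perm))
    baseline = float(np.mean(base_accs))
    rows = []
    for b in blocks:
        shuffled = float(np.mean(drop_accs[b]))
        rows.append(
            {"channel": b, "baseline_accuracy": baseline, "shuffled_accuracy": shuffled,
             "importance": baseline - shuffled}
        )
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
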