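"""Nearest-neighbor distance analysis and proximal/distal classification.

Distances are directed: for each query cell of type A, the Euclidean distance
(μm) to its nearest cell of type B. CD4+ T cells are split into those
proximal to C1QC+ RTMs and those distal at a threshold of 50 μm by default
(the whole-slide co-localization definition); marker contrasts then compare
activation-marker expression between the two labels on the z-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data import CellMap, validate_marker_matrix

__all__ = [
    "DistanceSummary",
    "nn_distances",
    "classify_proximal",
    "marker_contrast",
]

PROXIMAL, DISTAL = "proximal", "distal"


@dataclass
class DistanceSummary:
    """Per-query-cell nearest-neighbor distances for one (A, B) pair in one ROI."""

    table: pd.DataFrame  # cell_id (type A), distance
    type_a: str
    type_b: str
    key: tuple[str, str] | None = None
    group: str | None = None

    @property
    def median(self) -> float:
        return float(self.table["distance"].median())

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance"].to_numpy(dtype=float)


def nn_distances(cellmap: CellMap, type_a: str, type_b: str) -> DistanceSummary | None:
    """Distance from every type-A cell to its nearest type-B cell.

    With ``type_a == type_b`` the nearest *other* cell of the same type is
    used. Returns ``None`` (the ROI is missing for this pair) when either
    type is absent, or when A == B with a single cell of that type.
    """
    for t in (type_a, type_b):
        if t not in cellmap.vocabulary:
            raise ValueError(f"phenotype {t!r} not in vocabulary")
    mask_a = cellmap.phenotypes == type_a
    mask_b = cellmap.phenotypes == type_b
    if not mask_a.any() or not mask_b.any():
        return None
    same = type_a == type_b
    if same and mask_a.sum() < 2:
        return None
    coords_a = cellmap.coords[mask_a]
    coords_b = cellmap.coords[mask_b]
    tree = cKDTree(coords_b)
    if same:
        d, _ = tree.query(coords_a, k=2)
        dist = d[:, 1]
    else:
        dist, _ = tree.query(coords_a, k=1)
    table = pd.DataFrame({"cell_id": cellmap.cell_ids[mask_a], "distance": dist})
    return DistanceSummary(
        table=table, type_a=type_a, type_b=type_b, key=cellmap.key, group=cellmap.group
    )


def classify_proximal(summary: DistanceSummary, threshold: float = 50.0) -> pd.DataFrame:
    """Label each query cell proximal (distance strictly < threshold) or distal.

    Returns the summary table with a ``label`` column; counts are available
    via ``value_counts`` and an infinite threshold labels every cell proximal.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out = summary.table.copy()
    out["label"] = np.where(out["distance"] < threshold, PROXIMAL, DISTAL)
    return out


def marker_contrast(
    markers: pd.DataFrame,
    labels: pd.Series,
    channels: list[str] | None = None,
    cellmap: CellMap | None = None,
) -> pd.DataFrame:
    """Proximal-vs-distal marker contrast on the z-score scale.

    Each channel is z-scored across the labeled cells; the contrast is the
    mean z in the proximal group minus the mean z in the distal group
    (the heatmap convention). Raw means are emitted alongside. Channels with
    zero variance get z = 0 and a ``degenerate`` flag instead of NaNs.

    Parameters
    ----------
    markers:
        cell_id-indexed intensity matrix covering at least the labeled cells.
    labels:
        cell_id-indexed series with values "proximal"/"distal".
    channels:
        Channels to contrast (default: all columns). Unknown names raise.
    """
    if cellmap is not None:
        markers = validate_marker_matrix(markers, cellmap)
    if channels is None:
        channels = list(markers.columns)
    missing = [c for c in channels if c not in markers.columns]
    if missing:
        raise ValueError(f"requested channels absent from marker matrix: {missing}")
    labels = labels.dropna()
    n_prox = int((labels == PROXIMAL).sum())
    n_dist = int((labels == DISTAL).sum())
    if n_prox < 2 or n_dist < 2:
        raise ValueError(
            f"marker contrast needs >= 2 cells per label (proximal={n_prox}, distal={n_dist})"
        )
    X = markers.loc[labels.index, channels].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    degenerate = sd == 0
    safe_sd = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / safe_sd
    Z[:, degenerate] = 0.0
    is_prox = (labels == PROXIMAL).to_numpy()
    rows = []
    for j, ch in enumerate(channels):
        rows.append(
            {
                "channel": ch,
                "mean_proximal": X[is_prox, j].mean(),
                "mean_distal": X[~is_prox, j].mean(),
                "z_proximal": Z[is_prox, j].mean(),
                "z_distal": Z[~is_prox, j].mean(),
                "z_diff": Z[is_prox, j].mean() - Z[~is_prox, j].mean(),
                "degenerate": bool(degenerate[j]),
            }
        )
    return pd.DataFrame(rows)
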