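"""Cellular-neighborhood (CN) profiling and clustering.

A cell's neighborhood window is the cell itself plus its k nearest neighbors
(k=20 by default) by Euclidean distance; its profile is the fraction of the
window occupied by each phenotype. Profiles pooled across the whole cohort
are clustered with k-means into k_cn cellular neighborhoods, so CN identities
are comparable across samples and groups. An inertia sweep over candidate
k_cn values supports choosing the clustering resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import CellMap
from .enrichment import compute_roe
from .graph import knn_indices

__all__ = [
    "neighborhood_profiles",
    "pool_profiles",
    "CNAssignment",
    "cluster_neighborhoods",
    "k_sweep",
    "cn_group_enrichment",
]


def neighborhood_profiles(cellmap: CellMap, k_nn: int = 20) -> pd.DataFrame:
    """Per-cell window composition over the phenotype vocabulary.

    The window is the center cell plus its ``k_nn`` nearest neighbors,
    truncated to the whole ROI when it has fewer than ``k_nn + 1`` cells.
    Returns a frame indexed by cell_id with one column per vocabulary
    phenotype; rows are in [0, 1] and sum to 1.
    """
    if k_nn < 1:
        raise ValueError(f"k_nn must be >= 1, got {k_nn}")
    if cellmap.n_cells < 2:
        raise ValueError("neighborhood profiles need at least 2 cells")
    vocab = list(cellmap.vocabulary.names)
    codes = pd.Categorical(cellmap.phenotypes, categories=vocab).codes
    neigh = knn_indices(cellmap.coords, k_nn)
    window = np.hstack([np.arange(cellmap.n_cells)[:, None], neigh])  # center included
    window_codes = codes[window]
    counts = np.stack([(window_codes == p).sum(axis=1) for p in range(len(vocab))], axis=1)
    profiles = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(profiles, index=pd.Index(cellmap.cell_ids, name="cell_id"), columns=vocab)


def pool_profiles(
    cellmaps: Sequence[CellMap], k_nn: int = 20
) -> tuple[pd.DataFrame, pd.Series]:
    """Profiles for a whole cohort, plus the per-cell group label.

    The frame is indexed by (sample_id, roi_id, cell_id).
    """
    frames = []
    groups = []
    for cm in cellmaps:
        prof = neighborhood_profiles(cm, k_nn=k_nn)
        prof.index = pd.MultiIndex.from_arrays(
            [[cm.sample_id] * len(prof), [cm.roi_id] * len(prof), prof.index],
            names=["sample_id", "roi_id", "cell_id"],
        )
        frames.append(prof)
        groups.append(pd.Series(cm.group, index=prof.index))
    return pd.concat(frames), pd.concat(groups).rename("group")


@dataclass
class CNAssignment:
    """Result of clustering pooled neighborhood profiles."""

    labels: pd.Series  # per cell, CN label in 1..k_cn
    k_cn: int
    composition: pd.DataFrame  # CN x phenotype mean window composition
    inertia: float
    seed: int

    def abundances(self, groups: pd.Series) -> pd.DataFrame:
        """CN x group cell counts (groups aligned to the label index)."""
        df = pd.DataFrame({"cn": self.labels, "group": groups.loc[self.labels.index]})
        return df.pivot_table(index="cn", columns="group", aggfunc="size", fill_value=0)


def cluster_neighborhoods(
    profiles: pd.DataFrame, k_cn: int, seed: int = 0, n_init: int = 10
) -> CNAssignment:
    """k-means partition of composition vectors into k_cn cellular neighborhoods.

    Runs ``n_init`` restarts with a fixed seed so assignments are bitwise
    reproducible. CN labels are 1-based; the composition matrix holds each
    CN's mean profile (rows sum to 1).
    """
    if k_cn < 1:
        raise ValueError(f"k_cn must be >= 1, got {k_cn}")
    if k_cn > len(profiles):
        raise ValueError(f"k_cn={k_cn} exceeds the number of profiles ({len(profiles)})")
    X = profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k_cn, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    labels = pd.Series(raw + 1, index=profiles.index, name="cn")
    composition = (
        profiles.groupby(labels).mean().rename_axis(index="cn")
    )
    return CNAssignment(
        labels=labels, k_cn=k_cn, composition=composition, inertia=float(km.inertia_), seed=seed
    )


def k_sweep(
    profiles: pd.DataFrame, ks: Iterable[int] = (5, 10, 15, 20), seed: int = 0, n_init: int = 10
) -> pd.Series:
    """k-means inertia across candidate CN counts, to choose the resolution."""
    out = {k: cluster_neighborhoods(profiles, k, seed=seed, n_init=n_init).inertia for k in ks}
    return pd.Series(out, name="inertia").rename_axis("k_cn")


def cn_group_enrichment(assignment: CNAssignment, groups: pd.Series) -> pd.DataFrame:
    """Ro/e of CN labels across groups (tissue prevalence of each CN)."""
    return compute_roe(assignment.abundances(groups))
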