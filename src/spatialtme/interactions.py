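"""Permutation-based pairwise cell-cell interaction (PCI) testing.

For an ordered phenotype pair (A, B) the interaction statistic is the mean
number of B cells among the graph neighbors of each A cell, on the kNN union
graph of the ROI. The null distribution is built by shuffling phenotype
labels within the ROI while holding the graph (and per-label counts) fixed,
so the test asks whether A and B are closer (attraction) or farther apart
(avoidance) than their abundances alone explain. P-values use the standard
add-one permutation estimator and are therefore in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CellMap
from .graph import SpatialGraph, build_knn_graph

__all__ = ["InteractionResult", "interaction_test", "interaction_group_contrast"]


@dataclass
class InteractionResult:
    """Per-ordered-pair interaction statistics for one ROI."""

    table: pd.DataFrame  # pheno_a, pheno_b, observed, p_attraction, p_avoidance, n_a, n_b
    n_perm: int
    seed: int
    statistic: str
    key: tuple[str, str] | None = None
    group: str | None = None

    def matrix(self, value: str = "observed") -> pd.DataFrame:
        return self.table.pivot(index="pheno_a", columns="pheno_b", values=value)


def _pair_stats(
    edge_src: np.ndarray,
    edge_dst: np.ndarray,
    codes: np.ndarray,
    n_pheno: int,
    counts: np.ndarray,
    statistic: str,
) -> np.ndarray:
    """Statistic matrix S[a, b] from the directed edge list.

    S[a, b] = (number of directed edges from an a-cell to a b-cell),
    divided by the number of a-cells in "mean" mode.
    """
    pair_codes = codes[edge_src] * n_pheno + codes[edge_dst]
    flat = np.bincount(pair_codes, minlength=n_pheno * n_pheno)
    mat = flat.reshape(n_pheno, n_pheno).astype(float)
    if statistic == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = mat / counts[:, None]
    return mat


def interaction_test(
    cellmap: CellMap,
    graph: SpatialGraph | None = None,
    k: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: Literal["mean", "total"] = "mean",
) -> InteractionResult:
    """Label-permutation interaction test for every ordered phenotype pair.

    Parameters
    ----------
    cellmap:
        One ROI. At least two phenotypes must be present.
    graph:
        Prebuilt spatial graph; built with ``k`` nearest neighbors if omitted.
    n_perm:
        Number of label permutations for the null.
    statistic:
        "mean" (default) = mean count of B among each A cell's neighbors;
        "total" = total directed A->B neighbor-pair count.

    Pairs whose A or B phenotype is absent from the ROI are reported with
    missing (NaN) statistic and p-values rather than zeros.
    """
    if statistic not in ("mean", "total"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if graph is None:
        graph = build_knn_graph(cellmap, k=k)
    vocab = list(cellmap.vocabulary.names)
    n_pheno = len(vocab)
    codes = pd.Categorical(cellmap.phenotypes, categories=vocab).codes.astype(np.int64)
    counts = np.bincount(codes, minlength=n_pheno).astype(float)
    if (counts > 0).sum() < 2:
        raise ValueError("interaction test needs at least 2 phenotypes present")
    src, dst = graph.edge_arrays()

    obs = _pair_stats(src, dst, codes, n_pheno, counts, statistic)
    rng = np.random.default_rng(seed)
    ge = np.zeros_like(obs)
    le = np.zeros_like(obs)
    perm_codes = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        s = _pair_stats(src, dst, perm_codes, n_pheno, counts, statistic)
        ge += s >= obs
        le += s <= obs
    p_attr = (1.0 + ge) / (1.0 + n_perm)
    p_avoid = (1.0 + le) / (1.0 + n_perm)

    present = counts > 0
    rows = []
    for a in range(n_pheno):
        for b in range(n_pheno):
            defined = present[a] and present[b]
            rows.append(
                {
                    "pheno_a": vocab[a],
                    "pheno_b": vocab[b],
                    "observed": obs[a, b] if defined else np.nan,
                    "p_attraction": p_attr[a, b] if defined else np.nan,
                    "p_avoidance": p_avoid[a, b] if defined else np.nan,
                    "n_a": int(counts[a]),
                    "n_b": int(counts[b]),
                }
            )
    table = pd.DataFrame(rows)
    return InteractionResult(
        table=table,
        n_perm=n_perm,
        seed=seed,
        statistic=statistic,
        key=cellmap.key,
        group=cellmap.group,
    )


def interaction_group_contrast(
    results: Sequence[InteractionResult],
    group_a: str,
    group_b: str,
    eps: float = 1e-6,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """log2 fold change of mean interaction strength between two groups.

    For each ordered pair, the per-ROI observed statistics are averaged within
    each group (ignoring ROIs where the pair is undefined) and contrasted as
    log2((mean_A + eps) / (mean_B + eps)). Pairs undefined in every ROI of a
    group are reported missing. ``alpha`` flags pairs whose median attraction
    p-value within group_a is below the threshold (significant-square
    annotation); the contrast itself carries no test.
    """
    groups = {r.group for r in results}
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group {g!r} not present among results (have {sorted(groups)})")
    frames = []
    for r in results:
        t = r.table.copy()
        t["group"] = r.group
        frames.append(t)
    df = pd.concat(frames, ignore_index=True)
    pooled = (
        df.groupby(["pheno_a", "pheno_b", "group"])
        .agg(observed=("observed", "mean"), p_attraction=("p_attraction", "median"))
        .reset_index()
    )
    wide = pooled.pivot(index=["pheno_a", "pheno_b"], columns="group")
    mean_a = wide[("observed", group_a)]
    mean_b = wide[("observed", group_b)]
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": np.log2((mean_a + eps) / (mean_b + eps)),
            "significant_a": wide[("p_attraction", group_a)] <= alpha,
        }
    ).reset_index()
    out.loc[out["mean_a"].isna() | out["mean_b"].isna(), "log2fc"] = np.nan
    return out
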