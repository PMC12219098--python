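"""Fibroblast barrier score: interpositioning of RTM-adjacent fibroblasts
between CD4+ T cells and their nearest C1QC+ RTMs.

Construction, per ROI:

1. Build the 5-nearest-neighbor union graph with Euclidean edge lengths.
2. For each CD4+ T cell, compute weighted shortest-path distances to every
   C1QC+ RTM; the tied-nearest target set is all RTMs within a relative
   tolerance of the minimum graph distance.
3. Reconstruct one deterministic shortest path per tied RTM (at equal-length
   branch points the predecessor with the lowest cell_id is taken).
4. A path is "blocked" when its interior contains a fibroblast that shares a
   graph edge with at least one RTM (only fibroblasts clustered at the edge
   of the RTMs count; path endpoints never count).
5. The per-cell score is the fraction of tied-nearest paths blocked
   (``path_fraction`` mode; the worked schematic with three of four paths
   blocked scores 3/4) or the mean number of RTM-adjacent fibroblasts along
   the paths (``count`` mode). The image score is the mean over scored CD4
   cells; CD4 cells with no reachable RTM are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .data import CellMap, PhenotypeVocabulary
from .graph import SpatialGraph, build_knn_graph

__all__ = ["BarrierResult", "rtm_adjacent_fibroblasts", "barrier_scores"]


def rtm_adjacent_fibroblasts(
    graph: SpatialGraph, cellmap: CellMap, vocabulary: PhenotypeVocabulary | None = None
) -> set[str]:
    """Cell ids of barrier-source cells sharing a graph edge with >= 1 target cell.

    With the default role tags: fibroblasts directly adjacent (1 hop) to a
    C1QC+ RTM on the spatial graph. Returns an empty set when the ROI has no
    targets.
    """
    vocab = vocabulary or cellmap.vocabulary
    source, target, _ = vocab.require_barrier_roles()
    phen = cellmap.phenotypes
    target_idx = np.flatnonzero(phen == target)
    if len(target_idx) == 0:
        return set()
    is_target = np.zeros(len(phen), dtype=bool)
    is_target[target_idx] = True
    out: set[str] = set()
    for i in np.flatnonzero(phen == source):
        if is_target[graph.neighbors(i)].any():
            out.add(cellmap.cell_ids[i])
    return out


def _reconstruct_path(
    graph: SpatialGraph,
    dist_from_source: np.ndarray,
    source: int,
    target: int,
    tol: float,
) -> list[int]:
    """Backward walk from target to source along the shortest-path DAG.

    At each node the predecessor is any neighbor u with
    dist[u] + w(u, v) == dist[v] (within ``tol``); among candidates the one
    with the lowest cell_id is chosen, giving one deterministic path per
    (source, target) pair. Returns node indices source..target.
    """
    ids = graph.cell_ids
    A = graph.adjacency
    path = [target]
    v = target
    for _ in range(graph.n_nodes):
        if v == source:
            break
        nbrs = graph.neighbors(v)
        w = A.data[A.indptr[v] : A.indptr[v + 1]]
        slack = np.abs(dist_from_source[nbrs] + w - dist_from_source[v])
        cand = nbrs[slack <= tol]
        if len(cand) == 0:  # numerical dead end; widen once
            cand = nbrs[slack <= slack.min() + tol]
        v = int(cand[np.argmin(ids[cand])]) if len(cand) > 1 else int(cand[0])
        path.append(v)
    else:
        raise RuntimeError("shortest-path reconstruction did not terminate")
    path.reverse()
    return path


@dataclass
class BarrierResult:
    """Per-cell and per-image fibroblast barrier scores for one ROI."""

    per_cell: pd.DataFrame  # cell_id, n_tied_targets, score (NaN if unreachable)
    image_score: float  # NaN when no query or no target cells exist
    n_scored: int
    n_excluded: int  # query cells with no reachable target
    mode: str
    adjacent_fibroblasts: frozenset[str]
    reason: str | None = None
    key: tuple[str, str] | None = None
    group: str | None = None


def barrier_scores(
    cellmap: CellMap,
    k: int = 5,
    mode: Literal["path_fraction", "count"] = "path_fraction",
    tie_tol: float = 1e-9,
    weighted: bool = True,
    vocabulary: PhenotypeVocabulary | None = None,
    graph: SpatialGraph | None = None,
) -> BarrierResult:
    """Fibroblast barrier score of every CD4+ T cell and of the whole image.

    Parameters
    ----------
    k:
        Neighbors for the spatial graph (5, the construction's default).
    mode:
        ``path_fraction``: per-cell score = fraction of tied-nearest-RTM
        shortest paths whose interior contains an RTM-adjacent fibroblast
        (in [0, 1]); ``count``: mean number of such fibroblasts along the
        paths.
    tie_tol:
        Relative tolerance defining the tied-nearest target set and
        equal-length branches during path reconstruction.
    weighted:
        Use Euclidean edge lengths as path weights (default); ``False``
        counts hops instead.
    """
    if mode not in ("path_fraction", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    if tie_tol < 0:
        raise ValueError("tie_tol must be nonnegative")
    vocab = vocabulary or cellmap.vocabulary
    source, target, query = vocab.require_barrier_roles()
    phen = cellmap.phenotypes
    query_idx = np.flatnonzero(phen == query)
    target_idx = np.flatnonzero(phen == target)
    if len(query_idx) == 0 or len(target_idx) == 0:
        missing = query if len(query_idx) == 0 else target
        return BarrierResult(
            per_cell=pd.DataFrame(columns=["cell_id", "n_tied_targets", "score"]),
            image_score=float("nan"),
            n_scored=0,
            n_excluded=0,
            mode=mode,
            adjacent_fibroblasts=frozenset(),
            reason=f"no {missing} cells in ROI",
            key=cellmap.key,
            group=cellmap.group,
        )
    if graph is None:
        graph = build_knn_graph(cellmap, k=k)
    adj_fibs = rtm_adjacent_fibroblasts(graph, cellmap, vocab)
    adj_fib_idx = np.zeros(graph.n_nodes, dtype=bool)
    if adj_fibs:
        id_to_idx = {cid: i for i, cid in enumerate(cellmap.cell_ids)}
        adj_fib_idx[[id_to_idx[c] for c in adj_fibs]] = True

    W = graph.adjacency if weighted else graph.adjacency.sign()
    D = dijkstra(W, directed=False, indices=query_idx)

    rows = []
    scores = []
    n_excluded = 0
    for qi, q in enumerate(query_idx):
        d_targets = D[qi, target_idx]
        finite = np.isfinite(d_targets)
        if not finite.any():
            n_excluded += 1
            rows.append({"cell_id": cellmap.cell_ids[q], "n_tied_targets": 0, "score": np.nan})
            continue
        dmin = d_targets[finite].min()
        tol = tie_tol * max(dmin, 1.0)
        tied = target_idx[finite.nonzero()[0][d_targets[finite] <= dmin + tol]]
        per_path = []
        for t in tied:
            path = _reconstruct_path(graph, D[qi], int(q), int(t), tol=max(tol, 1e-9))
            interior = path[1:-1]
            hits = int(adj_fib_idx[interior].sum())
            per_path.append(min(hits, 1) if mode == "path_fraction" else hits)
        score = float(np.mean(per_path))
        scores.append(score)
        rows.append(
            {"cell_id": cellmap.cell_ids[q], "n_tied_targets": len(tied), "score": score}
        )
    per_cell = pd.DataFrame(rows)
    image = float(np.mean(scores)) if scores else float("nan")
    return BarrierResult(
        per_cell=per_cell,
        image_score=image,
        n_scored=len(scores),
        n_excluded=n_excluded,
        mode=mode,
        adjacent_fibroblasts=frozenset(adj_fibs),
        reason=None if scores else "no query cell can reach a target",
        key=cellmap.key,
        group=cellmap.group,
    )
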