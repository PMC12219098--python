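"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(n^2) scans, exhaustive path
enumeration via networkx, direct formula evaluation — and shares no code
with the implementations it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd


def brute_knn_adjacency(coords: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Undirected kNN-union edge set {(i, j), i < j} by full distance scan."""
    n = len(coords)
    kk = min(k, n - 1)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        d = [(math.dist(coords[i], coords[j]), j) for j in range(n) if j != i]
        d.sort()
        for _, j in d[:kk]:
            edges.add((min(i, j), max(i, j)))
    return edges


def brute_profiles(coords: np.ndarray, phenos: np.ndarray, vocab: list[str], k: int) -> np.ndarray:
    """Window composition per cell (center + k nearest), full distance scan."""
    n = len(coords)
    kk = min(k, n - 1)
    out = np.zeros((n, len(vocab)))
    for i in range(n):
        d = sorted((math.dist(coords[i], coords[j]), j) for j in range(n) if j != i)
        window = [i] + [j for _, j in d[:kk]]
        for j in window:
            out[i, vocab.index(phenos[j])] += 1
        out[i] /= len(window)
    return out


def brute_nn_distance(coords_a: np.ndarray, coords_b: np.ndarray, same: bool = False) -> np.ndarray:
    """Per-A-cell distance to nearest B cell; with same=True, A and B coincide."""
    out = []
    for i, p in enumerate(coords_a):
        ds = [
            math.dist(p, q)
            for j, q in enumerate(coords_b)
            if not (same and i == j)
        ]
        out.append(min(ds))
    return np.asarray(out)


def brute_roe(counts: pd.DataFrame) -> pd.DataFrame:
    """Elementwise O/E with the chi-square expectation, scalar loops."""
    O = counts.to_numpy(dtype=float)
    total = O.sum()
    out = np.zeros_like(O)
    for i in range(O.shape[0]):
        for j in range(O.shape[1]):
            e = O[i].sum() * O[:, j].sum() / total
            out[i, j] = O[i, j] / e
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def brute_barrier_per_cell(
    cellmap, graph, rel_tol: float = 1e-9
) -> dict[str, float]:
    """Path-fraction barrier scores via networkx exhaustive shortest paths.

    Nearest targets are tied by weighted graph distance; for each tied target
    all shortest paths are enumerated and the deterministic one (lowest
    cell_id at equal-length branch points, walking back from the target) is
    the path whose reversed cell_id sequence is lexicographically smallest.
    """
    source, target, query = cellmap.vocabulary.require_barrier_roles()
    g = graph.to_networkx()
    ids = graph.cell_ids
    phen = cellmap.phenotypes
    target_nodes = [i for i in range(len(ids)) if phen[i] == target]
    # RTM-adjacent fibroblasts by direct neighbor scan
    adjacent = set()
    for i in range(len(ids)):
        if phen[i] == source and any(phen[j] == target for j in g.neighbors(i)):
            adjacent.add(i)
    scores: dict[str, float] = {}
    for q in range(len(ids)):
        if phen[q] != query:
            continue
        lengths = nx.single_source_dijkstra_path_length(g, q, weight="length")
        reach = [(lengths[t], t) for t in target_nodes if t in lengths]
        if not reach:
            scores[ids[q]] = float("nan")
            continue
        dmin = min(d for d, _ in reach)
        tied = [t for d, t in reach if d <= dmin + rel_tol * max(dmin, 1.0)]
        indicators = []
        for t in tied:
            paths = list(nx.all_shortest_paths(g, q, t, weight="length"))
            chosen = min(paths, key=lambda p: tuple(ids[v] for v in reversed(p)))
            interior = chosen[1:-1]
            indicators.append(1.0 if any(v in adjacent for v in interior) else 0.0)
        scores[ids[q]] = float(np.mean(indicators))
    return scores


def clark_evans_z(coords: np.ndarray, width: float, height: float) -> float:
    """Clark–Evans aggregation z statistic with the Donnelly edge correction.

    Under complete spatial randomness z ~ N(0, 1); |z| > 1.96 rejects CSR at
    alpha = 0.05 (two-sided).
    """
    n = len(coords)
    if n < 2:
        raise ValueError("need >= 2 points")
    area = width * height
    perimeter = 2 * (width + height)
    r_obs = brute_nn_distance(coords, coords, same=True).mean()
    r_exp = 0.5 * math.sqrt(area / n) + (0.0514 + 0.041 / math.sqrt(n)) * perimeter / n
    se = math.sqrt(0.0703 * area / n**2 + 0.037 * perimeter * math.sqrt(area / n**5))
    return (r_obs - r_exp) / se
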