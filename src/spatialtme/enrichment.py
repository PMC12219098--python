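"""Ro/e tissue-distribution enrichment.

Ro/e is the ratio of the observed cell number of a (cell type, group)
combination to its expected number under independence, with the chi-square
expectation E[i, j] = rowsum_i * colsum_j / total. A value above 1 means the
type is observed in that group more often than random expectation — it is
enriched there; below 1, depleted. The statistic is reported descriptively,
without an attached significance test.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .data import CellMap, cell_frequencies

__all__ = ["compute_roe", "count_table", "roe_from_cellmaps"]


def _validate_table(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("Ro/e needs at least 2 rows and 2 columns")
    if not np.all(np.isfinite(arr)) or (arr < 0).any():
        raise ValueError("counts must be finite and nonnegative")
    zero_rows = counts.index[arr.sum(axis=1) == 0].tolist()
    zero_cols = counts.columns[arr.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        raise ValueError(
            f"all-zero rows/columns give zero expected counts: rows={zero_rows}, cols={zero_cols}"
        )
    return arr


def compute_roe(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected ratio table.

    Parameters
    ----------
    counts:
        Cell types (rows) x groups (columns), nonnegative. Raw cell counts are
        the default input; per-group frequencies are also accepted (the
        formula is scale-invariant per column block, see
        :func:`roe_from_cellmaps`).

    Returns
    -------
    DataFrame of the same shape with Roe[i, j] = O[i, j] / E[i, j] where
    E = outer(rowsums, colsums) / total.
    """
    arr = _validate_table(counts)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    return pd.DataFrame(arr / expected, index=counts.index, columns=counts.columns)


def count_table(
    cellmaps: Iterable[CellMap],
    row: str = "phenotype",
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phenotype x group cell-count table aggregated across ROIs.

    ``labels`` optionally fixes and orders the row set (defaults to the
    phenotypes present); columns are the group labels present, sorted.
    """
    records = []
    for cm in cellmaps:
        sub = cm.cells["phenotype"].value_counts()
        for pheno, n in sub.items():
            records.append((pheno, cm.group, int(n)))
    if not records:
        raise ValueError("no cells to tabulate")
    df = pd.DataFrame(records, columns=["phenotype", "group", "n"])
    table = df.pivot_table(index="phenotype", columns="group", values="n", aggfunc="sum", fill_value=0)
    if labels is not None:
        table = table.reindex(list(labels), fill_value=0)
    table.index.name = row
    return table.sort_index(axis=1)


def roe_from_cellmaps(
    cellmaps: Sequence[CellMap],
    input: Literal["counts", "frequency"] = "counts",
) -> pd.DataFrame:
    """Ro/e of phenotypes across groups, straight from a cohort.

    ``input="counts"`` (default) aggregates raw per-group cell counts;
    ``input="frequency"`` first converts each ROI to phenotype frequencies and
    averages them within each group before forming O/E, which removes the
    influence of unequal per-group cellularity. The two are identical when
    every group contributes the same total cell number.
    """
    if input == "counts":
        return compute_roe(count_table(cellmaps))
    if input == "frequency":
        per_group: dict[str, list[pd.Series]] = {}
        for cm in cellmaps:
            per_group.setdefault(cm.group, []).append(cell_frequencies(cm))
        table = pd.DataFrame(
            {g: pd.concat(fr, axis=1).mean(axis=1) for g, fr in sorted(per_group.items())}
        )
        table = table.loc[(table.sum(axis=1) > 0)]
        return compute_roe(table)
    raise ValueError(f"unknown input mode {input!r}")
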