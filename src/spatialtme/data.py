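"""Core containers and delimited-text I/O for segmented single-cell spatial data.

A :class:`CellMap` holds one region of interest (ROI) worth of segmented cells:
continuous Cartesian coordinates in micrometres, a phenotype label per cell
drawn from a closed :class:`PhenotypeVocabulary`, and sample/group metadata.
An optional :class:`MarkerMatrix` (a plain :class:`pandas.DataFrame`) carries
normalized per-cell marker intensities aligned to the same cells.

Coordinates are plain Euclidean μm with no image-axis conventions; ROI bounds
default to the axis-aligned bounding box of the cells and only matter to the
simulator and to plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeVocabulary",
    "DEFAULT_VOCABULARY",
    "CellMap",
    "cell_frequencies",
    "read_cell_table",
    "write_cell_table",
    "read_marker_table",
    "write_marker_table",
    "validate_marker_matrix",
    "to_anndata",
    "arcsinh_normalize",
    "CELL_TABLE_COLUMNS",
]

#: Required header of the cell-table CSV.
CELL_TABLE_COLUMNS = ("sample_id", "roi_id", "group", "cell_id", "x_um", "y_um", "phenotype")

#: The four clinical groups used throughout the documentation; all statistics
#: are group-label-agnostic and accept arbitrary strings.
PRESET_GROUPS = ("MSI_R", "MSI_NR", "MSS_R", "MSS_NR")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input table violates a container invariant."""


@dataclass(frozen=True)
class PhenotypeVocabulary:
    """Closed, ordered set of phenotype names with barrier-analysis role tags.

    The three roles map user phenotype labels onto the triad of the barrier
    analysis: ``barrier_source`` (fibroblasts, the obstructing type),
    ``barrier_target`` (C1QC+ resident tissue macrophages, the destination)
    and ``barrier_query`` (CD4+ T cells, the cells being scored).
    """

    names: tuple[str, ...]
    barrier_source: str | None = None
    barrier_target: str | None = None
    barrier_query: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValidationError("vocabulary must contain at least one phenotype")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("phenotype names must be unique")
        roles = {
            "barrier_source": self.barrier_source,
            "barrier_target": self.barrier_target,
            "barrier_query": self.barrier_query,
        }
        declared = [v for v in roles.values() if v is not None]
        for role, name in roles.items():
            if name is not None and name not in self.names:
                raise ValidationError(f"{role}={name!r} is not in the vocabulary")
        if len(set(declared)) != len(declared):
            raise ValidationError("a phenotype may carry at most one barrier role")

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def require_barrier_roles(self) -> tuple[str, str, str]:
        """Return (source, target, query) phenotypes, or raise if any is unset."""
        if None in (self.barrier_source, self.barrier_target, self.barrier_query):
            raise ValidationError(
                "barrier analysis needs barrier_source, barrier_target and "
                "barrier_query role tags on the vocabulary"
            )
        return self.barrier_source, self.barrier_target, self.barrier_query  # type: ignore[return-value]


#: Core phenotype set used by the simulator and the documentation examples.
DEFAULT_VOCABULARY = PhenotypeVocabulary(
    names=("Tumor", "Fibroblast", "C1QC_RTM", "CD4_T", "CD8_T", "B", "Other"),
    barrier_source="Fibroblast",
    barrier_target="C1QC_RTM",
    barrier_query="CD4_T",
)


@dataclass
class CellMap:
    """One ROI of segmented cells.

    ``cells`` has columns ``cell_id`` (unique within the ROI), ``x_um``,
    ``y_um`` and ``phenotype`` and is kept sorted by ``cell_id`` so every
    downstream computation is deterministic in the face of distance ties.
    """

    sample_id: str
    roi_id: str
    group: str
    cells: pd.DataFrame
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY
    bounds: tuple[float, float, float, float] | None = None  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        df = self.cells
        missing = [c for c in ("cell_id", "x_um", "y_um", "phenotype") if c not in df.columns]
        if missing:
            raise SchemaError(f"cells frame is missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError(f"ROI {self.key} has no cells")
        dup = df["cell_id"][df["cell_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate cell_id in ROI {self.key}: {dup}")
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError(f"non-finite coordinates in ROI {self.key}")
        unknown = sorted(set(df["phenotype"]) - set(self.vocabulary.names))
        if unknown:
            raise ValidationError(
                f"unknown phenotypes in ROI {self.key}: {unknown}; "
                "declare them in the vocabulary or load with other_label="
            )
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            if (xy[:, 0] < xmin).any() or (xy[:, 0] > xmax).any() or (
                xy[:, 1] < ymin
            ).any() or (xy[:, 1] > ymax).any():
                raise ValidationError(f"cells outside declared bounds in ROI {self.key}")
        df = df.sort_values("cell_id", kind="stable").reset_index(drop=True)
        object.__setattr__(self, "cells", df)

    # -- convenience accessors -------------------------------------------------
    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.roi_id)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def phenotypes(self) -> np.ndarray:
        return self.cells["phenotype"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def bounding_box(self) -> tuple[float, float, float, float]:
        if self.bounds is not None:
            return self.bounds
        xy = self.coords
        return (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())

    def subset(self, mask: np.ndarray) -> "CellMap":
        """A new CellMap restricted to ``mask`` (boolean over cells)."""
        return replace(self, cells=self.cells.loc[np.asarray(mask)].reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out.insert(0, "group", self.group)
        out.insert(0, "roi_id", self.roi_id)
        out.insert(0, "sample_id", self.sample_id)
        return out[list(CELL_TABLE_COLUMNS)]


def cell_frequencies(cellmap: CellMap) -> pd.Series:
    """Per-phenotype cell frequency: cell count over total cell (nuclei) count.

    Absent phenotypes are reported as 0 so the result always covers the full
    vocabulary in order and sums to 1.
    """
    counts = cellmap.cells["phenotype"].value_counts()
    freq = pd.Series(0.0, index=list(cellmap.vocabulary.names), name="frequency")
    freq.loc[counts.index] = counts.to_numpy(dtype=float)
    return freq / freq.sum()


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY,
    other_label: str | None = None,
) -> list[CellMap]:
    """Read a cohort cell-table CSV into a list of per-ROI :class:`CellMap`.

    Parameters
    ----------
    path:
        CSV with header ``sample_id, roi_id, group, cell_id, x_um, y_um,
        phenotype`` (UTF-8, "." decimal).
    vocabulary:
        Closed phenotype vocabulary; labels outside it are rejected.
    other_label:
        If given (it must be in the vocabulary), unknown phenotype labels are
        mapped to it instead of raising.

    Returns
    -------
    list of CellMap, ordered by (sample_id, roi_id); cells ordered by cell_id.
    """
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "roi_id": str, "group": str, "cell_id": str, "phenotype": str},
        float_precision="round_trip",
    )
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} is missing required columns: {missing}")
    if other_label is not None:
        if other_label not in vocabulary:
            raise ValidationError(f"other_label {other_label!r} is not in the vocabulary")
        known = df["phenotype"].isin(vocabulary.names)
        df.loc[~known, "phenotype"] = other_label
    out: list[CellMap] = []
    for (sample_id, roi_id), sub in df.groupby(["sample_id", "roi_id"], sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"ROI ({sample_id}, {roi_id}) has conflicting group labels: {groups}")
        out.append(
            CellMap(
                sample_id=sample_id,
                roi_id=roi_id,
                group=groups[0],
                cells=sub[["cell_id", "x_um", "y_um", "phenotype"]].reset_index(drop=True),
                vocabulary=vocabulary,
            )
        )
    return out


def write_cell_table(cellmaps: Iterable[CellMap], path: str | Path) -> None:
    """Write ROIs to one cohort CSV; inverse of :func:`read_cell_table`.

    Output ordering is canonical (sample_id, roi_id, cell_id), so
    write(read(x)) is idempotent for text-representable values.
    """
    frames = [cm.to_frame() for cm in cellmaps]
    if not frames:
        raise ValidationError("no ROIs to write")
    pd.concat(frames, ignore_index=True).sort_values(
        ["sample_id", "roi_id", "cell_id"], kind="stable"
    ).to_csv(path, index=False)


def validate_marker_matrix(markers: pd.DataFrame, cellmap: CellMap) -> pd.DataFrame:
    """Check a marker matrix against a CellMap and return it row-aligned.

    The row set must equal the ROI's cell set, channel names must be unique
    and values must be present (no NaN) and nonnegative after load.
    """
    if markers.columns.duplicated().any():
        raise ValidationError("duplicate channel names in marker matrix")
    want = pd.Index(cellmap.cell_ids)
    have = markers.index
    if set(have) != set(want):
        miss = sorted(set(want) - set(have))[:5]
        extra = sorted(set(have) - set(want))[:5]
        raise ValidationError(
            f"marker rows do not match ROI {cellmap.key} cells "
            f"(missing e.g. {miss}, extra e.g. {extra})"
        )
    aligned = markers.loc[want]
    if aligned.isna().to_numpy().any():
        raise ValidationError(f"missing marker values in ROI {cellmap.key}")
    if (aligned.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"negative marker intensities in ROI {cellmap.key}")
    return aligned


def read_marker_table(
    path: str | Path, cellmaps: Sequence[CellMap] | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """Read a cohort marker CSV (sample_id, roi_id, cell_id + one column per channel).

    Returns a dict keyed by (sample_id, roi_id) with cell_id-indexed frames.
    When ``cellmaps`` is given, each matrix is validated and row-aligned.
    """
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "roi_id": str, "cell_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in ("sample_id", "roi_id", "cell_id") if c not in df.columns]
    if missing:
        raise SchemaError(f"marker table {path} is missing required columns: {missing}")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for key, sub in df.groupby(["sample_id", "roi_id"], sort=True):
        mat = sub.drop(columns=["sample_id", "roi_id"]).set_index("cell_id")
        out[key] = mat
    if cellmaps is not None:
        by_key = {cm.key: cm for cm in cellmaps}
        for key in list(out):
            if key in by_key:
                out[key] = validate_marker_matrix(out[key], by_key[key])
    return out


def write_marker_table(
    markers: Mapping[tuple[str, str], pd.DataFrame], path: str | Path
) -> None:
    frames = []
    for (sample_id, roi_id) in sorted(markers):
        mat = markers[(sample_id, roi_id)].sort_index()
        sub = mat.reset_index()
        sub.insert(0, "roi_id", roi_id)
        sub.insert(0, "sample_id", sample_id)
        frames.append(sub)
    if not frames:
        raise ValidationError("no marker matrices to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def arcsinh_normalize(markers: pd.DataFrame, cofactor: float = 5.0) -> pd.DataFrame:
    """Optional arcsinh(x / cofactor) transform for raw intensities.

    Provided as a documented convenience for users loading unnormalized data;
    loaders otherwise accept intensities as already normalized.
    """
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.arcsinh(markers / cofactor)


def to_anndata(
    cellmaps: Sequence[CellMap],
    markers: Mapping[tuple[str, str], pd.DataFrame] | None = None,
):
    """Export a cohort into one AnnData (H5AD-dialect) single-cell container.

    obs carries sample/ROI/group/phenotype, ``obsm['spatial']`` the μm
    coordinates and X the marker intensities (zeros when none are supplied).
    """
    import anndata as ad

    obs_frames = []
    xs = []
    channels: pd.Index | None = None
    for cm in cellmaps:
        obs = cm.cells[["cell_id", "phenotype"]].copy()
        obs["sample_id"] = cm.sample_id
        obs["roi_id"] = cm.roi_id
        obs["group"] = cm.group
        obs.index = [f"{cm.sample_id}|{cm.roi_id}|{cid}" for cid in cm.cells["cell_id"]]
        obs_frames.append(obs.join(cm.cells[["x_um", "y_um"]].set_axis(obs.index)))
        if markers is not None:
            mat = validate_marker_matrix(markers[cm.key], cm)
            if channels is None:
                channels = mat.columns
            elif not channels.equals(mat.columns):
                raise ValidationError("inconsistent channel sets across ROIs")
            xs.append(mat.to_numpy(dtype=float))
    obs_all = pd.concat(obs_frames)
    spatial = obs_all[["x_um", "y_um"]].to_numpy(dtype=float)
    if markers is not None:
        X = np.vstack(xs)
        var = pd.DataFrame(index=list(channels))  # type: ignore[arg-type]
    else:
        X = np.zeros((len(obs_all), 0))
        var = pd.DataFrame(index=pd.Index([], name="channel"))
    adata = ad.AnnData(X=X, obs=obs_all.drop(columns=["x_um", "y_um"]), var=var)
    adata.obsm["spatial"] = spatial
    return adata
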