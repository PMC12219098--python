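"""Synthetic spatial cohorts with planted tumor-microenvironment topology.

The generator emulates the statistical structure the downstream analyses
assume, at the scale of the motivating cohort: 1 mm² ROIs, ~25 samples in
four clinical groups with two ROIs each, a core phenotype set, and ~1500
cells per ROI. Three planted effects make every analysis testable with known
ground truth:

* **Colocalization** — C1QC+ RTMs and CD4+ T cells are Thomas cluster
  processes; with group-dependent probability ``p_share`` a CD4 cluster is
  seeded at an RTM cluster's parent point, producing tunable cross-type
  attraction (responder-like groups share most parents).
* **Fibroblast barriers** — with group-dependent probability ``p_barrier``
  an RTM parent is encircled by a fibroblast arc of radius ``ring_radius``
  and angular coverage ``ring_coverage`` (non-responder-like groups ring
  most parents), creating geometrically computable blocked paths.
* **Proximity-dependent activation** — CD4+ T cells within ``d_act`` μm of
  an RTM receive an additive boost on the activation channels of an
  otherwise phenotype-conditional lognormal marker model.

All remaining phenotypes are homogeneous Poisson backgrounds. Per-ROI random
streams are derived from the master seed with ``numpy.random.SeedSequence``
spawn keys, so streams are reproducible and non-overlapping.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (
    DEFAULT_VOCABULARY,
    CellMap,
    PhenotypeVocabulary,
    write_cell_table,
    write_marker_table,
)

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "Cohort",
    "generate_roi",
    "generate_cohort",
    "csr_cellmap",
    "two_block_cellmap",
]

DEFAULT_CHANNELS = (
    "CD4", "CD8a", "CD20", "CD68", "C1QC", "aSMA",
    "PanCK", "CD38", "CD57", "GZMB", "TNFa", "PD1",
)

#: Lineage channels elevated in their own phenotype; everything else sits on
#: a common low background. Values are lognormal mu parameters.
_LINEAGE_MU = {
    "CD4_T": {"CD4": 2.0},
    "CD8_T": {"CD8a": 2.0},
    "B": {"CD20": 2.0},
    "C1QC_RTM": {"CD68": 2.0, "C1QC": 2.0},
    "Fibroblast": {"aSMA": 2.0},
    "Tumor": {"PanCK": 2.0},
}
_BACKGROUND_MU = 0.5


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sample count and planted-effect intensities."""

    n_samples: int
    p_share: float  # probability a CD4 cluster shares an RTM parent
    p_barrier: float  # probability an RTM parent gets a fibroblast ring

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for p in (self.p_share, self.p_barrier):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


#: Responder-like: strong RTM-CD4 colocalization, few barriers.
R_SPEC = GroupSpec(n_samples=5, p_share=0.8, p_barrier=0.1)
#: Non-responder-like: weak colocalization, frequent fibroblast rings.
NR_SPEC = GroupSpec(n_samples=5, p_share=0.15, p_barrier=0.8)


def _default_groups() -> dict[str, GroupSpec]:
    """The motivating cohort: 25 samples, four groups, two ROIs each."""
    return {
        "MSI_R": GroupSpec(n_samples=5, p_share=0.8, p_barrier=0.1),
        "MSS_R": GroupSpec(n_samples=8, p_share=0.8, p_barrier=0.1),
        "MSI_NR": GroupSpec(n_samples=4, p_share=0.15, p_barrier=0.8),
        "MSS_NR": GroupSpec(n_samples=8, p_share=0.15, p_barrier=0.8),
    }


def _default_background() -> dict[str, float]:
    # cells per mm²; clustered types keep a small homogeneous background so
    # they are never entirely absent from an ROI
    return {
        "Tumor": 600.0,
        "Other": 200.0,
        "Fibroblast": 100.0,
        "CD8_T": 100.0,
        "B": 80.0,
        "CD4_T": 50.0,
        "C1QC_RTM": 20.0,
    }


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with the study conditions as defaults."""

    roi_width: float = 1000.0  # μm (1 mm² ROI)
    roi_height: float = 1000.0
    rois_per_sample: int = 2
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    background_density: dict[str, float] = field(default_factory=_default_background)
    # Thomas cluster processes; RTM clusters are compact so a ring at
    # ring_radius encloses essentially all offspring (P(|r| > 25 | sigma=8)
    # < 1%), which is what makes the planted barriers geometrically real
    n_rtm_parents: int = 10
    rtm_offspring_mean: float = 20.0
    rtm_sigma: float = 8.0  # μm offspring dispersion
    n_cd4_parents: int = 12
    cd4_offspring_mean: float = 15.0
    cd4_sigma: float = 20.0
    # fibroblast rings; arc spacing (~7 μm) is below the typical 5-NN edge
    # length so paths crossing the annulus hop through ring cells
    ring_radius: float = 25.0  # μm
    ring_coverage: float = 0.9  # fraction of the circle covered by the arc
    ring_points: int = 24  # fibroblasts on a full circle (scaled by coverage)
    ring_jitter: float = 2.0  # radial jitter sd, μm
    # marker model
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    marker_sigma: float = 0.4  # lognormal sigma, all channels
    activation_channels: tuple[str, ...] = ("CD38", "CD57", "GZMB", "TNFa", "PD1")
    activation_boost: float = 2.0  # additive intensity on activation channels
    d_act: float = 50.0  # μm, activation range around RTMs
    #: additive shift on the lognormal mu of given channels for all cells of a
    #: group; used to plant group-informative channels
    group_marker_mu_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        for name, rate in self.background_density.items():
            if rate < 0:
                raise ValueError(f"negative background density for {name}")
            if name not in self.vocabulary:
                raise ValueError(f"background phenotype {name!r} not in vocabulary")
        for v, label in ((self.rtm_sigma, "rtm_sigma"), (self.cd4_sigma, "cd4_sigma"),
                         (self.ring_radius, "ring_radius"), (self.d_act, "d_act")):
            if v <= 0:
                raise ValueError(f"{label} must be positive")
        if not 0.0 <= self.ring_coverage <= 1.0:
            raise ValueError("ring_coverage must lie in [0, 1]")

    # -- presets ---------------------------------------------------------------
    @classmethod
    def rnr_preset(cls, n_samples_per_group: int = 5, **kwargs) -> "SimulationConfig":
        """Two-group responder/non-responder design (10 ROIs per group by default)."""
        groups = {
            "R": GroupSpec(n_samples_per_group, R_SPEC.p_share, R_SPEC.p_barrier),
            "NR": GroupSpec(n_samples_per_group, NR_SPEC.p_share, NR_SPEC.p_barrier),
        }
        return cls(groups=groups, **kwargs)

    @classmethod
    def homogeneous_preset(cls, **kwargs) -> "SimulationConfig":
        """No planted structure: every phenotype a homogeneous Poisson background."""
        groups = {"A": GroupSpec(5, 0.0, 0.0), "B": GroupSpec(5, 0.0, 0.0)}
        base = dict(
            groups=groups,
            n_rtm_parents=0,
            n_cd4_parents=0,
            activation_boost=0.0,
            background_density={**_default_background(), "C1QC_RTM": 150.0, "CD4_T": 200.0},
        )
        base.update(kwargs)
        return cls(**base)

    # -- YAML round trip -------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["groups"] = {g: asdict(s) for g, s in self.groups.items()}
        d["vocabulary"] = {
            "names": list(self.vocabulary.names),
            "barrier_source": self.vocabulary.barrier_source,
            "barrier_target": self.vocabulary.barrier_target,
            "barrier_query": self.vocabulary.barrier_query,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = {g: GroupSpec(**s) for g, s in d["groups"].items()}
        if "vocabulary" in d:
            v = d["vocabulary"]
            d["vocabulary"] = PhenotypeVocabulary(names=tuple(v["names"]),
                                                  barrier_source=v.get("barrier_source"),
                                                  barrier_target=v.get("barrier_target"),
                                                  barrier_query=v.get("barrier_query"))
        for key in ("channels", "activation_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _uniform_points(rng: np.random.Generator, n: int, w: float, h: float) -> np.ndarray:
    return rng.uniform([0.0, 0.0], [w, h], size=(n, 2))


def _thomas_offspring(
    rng: np.random.Generator, parents: np.ndarray, mean: float, sigma: float, w: float, h: float
) -> np.ndarray:
    pts = []
    for p in parents:
        n = rng.poisson(mean)
        if n:
            pts.append(p + rng.normal(0.0, sigma, size=(n, 2)))
    if not pts:
        return np.empty((0, 2))
    out = np.vstack(pts)
    return np.clip(out, [0.0, 0.0], [w, h])


def generate_roi(
    config: SimulationConfig,
    group: str,
    seed: int | np.random.SeedSequence,
    sample_id: str = "S01",
    roi_id: str = "ROI1",
) -> tuple[CellMap, pd.DataFrame, dict]:
    """Generate one ROI: a CellMap, an aligned marker matrix, and ground truth.

    The ground-truth dict records realized parent locations, shared-parent
    assignments, ring-fibroblast cell ids and activation-boosted CD4 ids, so
    tests can check planted effects geometrically.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r} (configured: {sorted(config.groups)})")
    group_spec = config.groups[group]
    w, h = config.roi_width, config.roi_height
    total_intensity = sum(config.background_density.values()) + config.n_rtm_parents + config.n_cd4_parents
    if total_intensity <= 0:
        raise ValueError("configuration generates no cells (zero total intensity)")
    rng = np.random.default_rng(seed)

    coords_list: list[np.ndarray] = []
    phen_list: list[str] = []

    # homogeneous backgrounds
    area_mm2 = (w / 1000.0) * (h / 1000.0)
    for pheno in config.vocabulary.names:
        rate = config.background_density.get(pheno, 0.0)
        n = rng.poisson(rate * area_mm2)
        if n:
            coords_list.append(_uniform_points(rng, n, w, h))
            phen_list.extend([pheno] * n)

    # Thomas clusters: RTMs, then CD4s sharing parents with probability p_share
    margin = config.ring_radius + 2 * config.rtm_sigma
    lo, hi = min(margin, w / 2), max(w - margin, w / 2)
    rtm_parents = rng.uniform([lo, lo], [hi, hi], size=(config.n_rtm_parents, 2)) \
        if config.n_rtm_parents else np.empty((0, 2))
    rtm_pts = _thomas_offspring(rng, rtm_parents, config.rtm_offspring_mean, config.rtm_sigma, w, h)
    if len(rtm_pts):
        coords_list.append(rtm_pts)
        phen_list.extend(["C1QC_RTM"] * len(rtm_pts))

    shared_flags = []
    cd4_parents = []
    for _ in range(config.n_cd4_parents):
        if len(rtm_parents) and rng.random() < group_spec.p_share:
            cd4_parents.append(rtm_parents[rng.integers(len(rtm_parents))])
            shared_flags.append(True)
        else:
            cd4_parents.append(rng.uniform([0.0, 0.0], [w, h]))
            shared_flags.append(False)
    cd4_parents = np.asarray(cd4_parents) if cd4_parents else np.empty((0, 2))
    cd4_pts = _thomas_offspring(rng, cd4_parents, config.cd4_offspring_mean, config.cd4_sigma, w, h)
    if len(cd4_pts):
        coords_list.append(cd4_pts)
        phen_list.extend(["CD4_T"] * len(cd4_pts))

    # fibroblast rings (barriers) around RTM parents
    ring_start = len(np.vstack(coords_list)) if coords_list else 0
    ringed_parents = []
    ring_pts = []
    n_arc = max(3, int(round(config.ring_points * config.ring_coverage)))
    for p in rtm_parents:
        if rng.random() < group_spec.p_barrier:
            ringed_parents.append(p.tolist())
            theta0 = rng.uniform(0, 2 * np.pi)
            thetas = theta0 + np.linspace(0, 2 * np.pi * config.ring_coverage, n_arc, endpoint=False)
            radii = config.ring_radius + rng.normal(0, config.ring_jitter, size=n_arc)
            pts = p + np.stack([radii * np.cos(thetas), radii * np.sin(thetas)], axis=1)
            ring_pts.append(np.clip(pts, [0.0, 0.0], [w, h]))
    if ring_pts:
        ring_arr = np.vstack(ring_pts)
        coords_list.append(ring_arr)
        phen_list.extend(["Fibroblast"] * len(ring_arr))

    coords = np.vstack(coords_list)
    n = len(coords)
    if n == 0:
        raise ValueError("configuration generated an empty ROI")
    width = max(4, len(str(n)))
    cell_ids = np.array([f"c{i:0{width}d}" for i in range(n)])
    ring_ids = cell_ids[ring_start:][np.asarray(phen_list[ring_start:]) == "Fibroblast"] \
        if ring_pts else np.array([], dtype=str)

    cells = pd.DataFrame(
        {"cell_id": cell_ids, "x_um": coords[:, 0], "y_um": coords[:, 1], "phenotype": phen_list}
    )
    cellmap = CellMap(
        sample_id=sample_id, roi_id=roi_id, group=group, cells=cells,
        vocabulary=config.vocabulary, bounds=(0.0, 0.0, w, h),
    )

    markers, boosted_ids = _simulate_markers(config, cellmap, group, rng)
    ground_truth = {
        "group": group,
        "seed_state": np.random.SeedSequence(seed).generate_state(4).tolist()
        if isinstance(seed, int) else seed.generate_state(4).tolist(),
        "rtm_parents": rtm_parents.tolist(),
        "cd4_parents": cd4_parents.tolist(),
        "cd4_parent_shared": shared_flags,
        "ringed_parents": ringed_parents,
        "ring_fibroblast_ids": sorted(ring_ids.tolist()),
        "activation_boosted_ids": sorted(boosted_ids),
    }
    return cellmap, markers, ground_truth


def _simulate_markers(
    config: SimulationConfig, cellmap: CellMap, group: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    """Phenotype-conditional lognormal intensities + proximity activation boost."""
    n = cellmap.n_cells
    phen = cellmap.phenotypes
    shift = config.group_marker_mu_shift.get(group, {})
    X = np.empty((n, len(config.channels)))
    for j, ch in enumerate(config.channels):
        mu = np.full(n, _BACKGROUND_MU)
        for pheno, chans in _LINEAGE_MU.items():
            if ch in chans:
                mu[phen == pheno] = chans[ch]
        mu += shift.get(ch, 0.0)
        X[:, j] = rng.lognormal(mean=mu, sigma=config.marker_sigma)

    boosted: list[str] = []
    if config.activation_boost != 0.0:
        cd4_mask = phen == "CD4_T"
        rtm_mask = phen == "C1QC_RTM"
        if cd4_mask.any() and rtm_mask.any():
            from scipy.spatial import cKDTree

            tree = cKDTree(cellmap.coords[rtm_mask])
            d, _ = tree.query(cellmap.coords[cd4_mask], k=1)
            near = np.flatnonzero(cd4_mask)[d < config.d_act]
            for ch in config.activation_channels:
                if ch in config.channels:
                    X[near, config.channels.index(ch)] += config.activation_boost
            boosted = cellmap.cell_ids[near].tolist()
    markers = pd.DataFrame(X, index=pd.Index(cellmap.cell_ids, name="cell_id"),
                           columns=list(config.channels))
    return markers, boosted


@dataclass
class Cohort:
    """A generated cohort: ROIs, aligned marker matrices and ground truth."""

    cellmaps: list[CellMap]
    markers: dict[tuple[str, str], pd.DataFrame]
    ground_truth: dict[str, dict]
    config: SimulationConfig
    master_seed: int

    def groups(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples([cm.key for cm in self.cellmaps],
                                        names=["sample_id", "roi_id"])
        return pd.Series([cm.group for cm in self.cellmaps], index=idx, name="group")

    def by_group(self, group: str) -> list[CellMap]:
        return [cm for cm in self.cellmaps if cm.group == group]

    def write(self, out_dir: str | Path) -> None:
        """Emit cells.csv, markers.csv and ground_truth.json."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cell_table(self.cellmaps, out / "cells.csv")
        write_marker_table(self.markers, out / "markers.csv")
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=1))


def generate_cohort(config: SimulationConfig, master_seed: int = 0) -> Cohort:
    """Generate every sample and ROI of the configured cohort.

    Per-ROI streams come from ``SeedSequence(master_seed,
    spawn_key=(sample_index, roi_index))`` with samples enumerated globally in
    group order — a stable derivation that keeps streams disjoint within and
    across master seeds.
    """
    cellmaps: list[CellMap] = []
    markers: dict[tuple[str, str], pd.DataFrame] = {}
    ground_truth: dict[str, dict] = {}
    sample_index = 0
    for group in sorted(config.groups):
        for s in range(config.groups[group].n_samples):
            sample_id = f"{group}_{s + 1:02d}"
            for r in range(config.rois_per_sample):
                roi_id = f"ROI{r + 1}"
                ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(sample_index, r))
                cm, mk, gt = generate_roi(config, group, ss, sample_id=sample_id, roi_id=roi_id)
                cellmaps.append(cm)
                markers[cm.key] = mk
                ground_truth[f"{sample_id}|{roi_id}"] = gt
            sample_index += 1
    return Cohort(cellmaps=cellmaps, markers=markers, ground_truth=ground_truth,
                  config=config, master_seed=master_seed)


def informative_channel_config(
    channel: str = "GZMB",
    shift: float = 0.8,
    n_samples: tuple[int, int] = (13, 12),
) -> SimulationConfig:
    """A 50-ROI two-group design where one channel carries the group signal.

    Both groups are homogeneous Poisson tissue with identical composition; the
    named channel's lognormal mu is shifted in group "B", so its summary
    features are a noisy copy of the group label while every other channel is
    pure noise. Used to validate permutation channel importance.
    """
    cfg = SimulationConfig.homogeneous_preset(
        background_density={
            "Tumor": 120.0, "Other": 40.0, "Fibroblast": 30.0,
            "CD8_T": 25.0, "B": 15.0, "CD4_T": 40.0, "C1QC_RTM": 30.0,
        },
        group_marker_mu_shift={"B": {channel: shift}},
    )
    cfg.groups = {"A": GroupSpec(n_samples[0], 0.0, 0.0), "B": GroupSpec(n_samples[1], 0.0, 0.0)}
    return cfg


# ---------------------------------------------------------------------------
# Small constructors used by calibration and clustering tests
# ---------------------------------------------------------------------------

def csr_cellmap(
    n_cells: int,
    phenotypes: Sequence[str],
    seed: int,
    probs: Sequence[float] | None = None,
    width: float = 1000.0,
    height: float = 1000.0,
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY,
    sample_id: str = "CSR",
    roi_id: str = "ROI1",
    group: str = "A",
) -> CellMap:
    """Complete spatial randomness: uniform positions, iid phenotype labels."""
    rng = np.random.default_rng(seed)
    coords = _uniform_points(rng, n_cells, width, height)
    labels = rng.choice(list(phenotypes), size=n_cells, p=probs)
    width_digits = max(4, len(str(n_cells)))
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:0{width_digits}d}" for i in range(n_cells)],
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "phenotype": labels,
        }
    )
    return CellMap(sample_id=sample_id, roi_id=roi_id, group=group, cells=cells,
                   vocabulary=vocabulary, bounds=(0.0, 0.0, width, height))


def two_block_cellmap(
    n_per_block: int = 60,
    seed: int = 0,
    sample_id: str = "BLOCK",
    roi_id: str = "ROI1",
    group: str = "A",
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY,
) -> tuple[CellMap, pd.Series]:
    """Two spatially separated pure niches: a tumor block and a fibroblast block.

    The blocks sit far apart relative to the neighborhood window, so every
    cell's kNN window stays within its own block and the planted partition is
    exactly recoverable. Returns the CellMap and the per-cell block label.
    """
    rng = np.random.default_rng(seed)
    left = rng.uniform([0.0, 0.0], [250.0, 1000.0], size=(n_per_block, 2))
    right = rng.uniform([750.0, 0.0], [1000.0, 1000.0], size=(n_per_block, 2))
    coords = np.vstack([left, right])
    phen = ["Tumor"] * n_per_block + ["Fibroblast"] * n_per_block
    blocks = ["tumor_niche"] * n_per_block + ["fibroblast_niche"] * n_per_block
    ids = [f"c{i:04d}" for i in range(2 * n_per_block)]
    cells = pd.DataFrame({"cell_id": ids, "x_um": coords[:, 0], "y_um": coords[:, 1], "phenotype": phen})
    cm = CellMap(sample_id=sample_id, roi_id=roi_id, group=group, cells=cells,
                 vocabulary=vocabulary, bounds=(0.0, 0.0, 1000.0, 1000.0))
    block_labels = pd.Series(blocks, index=pd.Index(ids, name="cell_id"), name="block")
    return cm, block_labels.loc[cm.cell_ids]
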