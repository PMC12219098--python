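"""CD4 -> RTM nearest-neighbor distances, proximal/distal split, marker contrast.

Findings on the default cohort: median CD4->RTM distance is several-fold
shorter in R than NR; the proximal CD4 fraction (<50 μm) is enriched in R
(Ro/e > 1); proximal CD4 cells show positive z-contrasts on the activation
channels (CD38, CD57, GZMB, TNFa, PD1). Writes distance_medians.csv,
proximal_roe.csv and activation_contrast.csv.
"""

from pathlib import Path

import pandas as pd

from spatialtme import (
    classify_proximal,
    compute_roe,
    marker_contrast,
    nn_distances,
    read_cell_table,
    read_marker_table,
)

ROOT = Path(__file__).resolve().parents[1]
ACTIVATION = ["CD38", "CD57", "GZMB", "TNFa", "PD1"]


def main():
    base = ROOT / "scratch" / "cohort"
    if not (base / "cells.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cellmaps = read_cell_table(base / "cells.csv")
    markers = read_marker_table(base / "markers.csv", cellmaps)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    rows, prox_counts, contrasts = [], {}, []
    for cm in cellmaps:
        s = nn_distances(cm, "CD4_T", "C1QC_RTM")
        if s is None:
            continue
        lab = classify_proximal(s, threshold=50.0)
        rows.append({"sample_id": cm.sample_id, "roi_id": cm.roi_id, "group": cm.group,
                     "median_um": s.median, "n_cd4": len(s.table),
                     "n_proximal": int((lab.label == "proximal").sum())})
        c = prox_counts.setdefault(cm.group, [0, 0])
        c[0] += int((lab.label == "proximal").sum())
        c[1] += int((lab.label == "distal").sum())
        series = lab.set_index("cell_id")["label"]
        if (series == "proximal").sum() >= 2 and (series == "distal").sum() >= 2:
            mc = marker_contrast(markers[cm.key], series, ACTIVATION)
            mc.insert(0, "group", cm.group)
            contrasts.append(mc)

    med = pd.DataFrame(rows)
    med.to_csv(out / "distance_medians.csv", index=False)
    print(med.groupby("group")["median_um"].median().round(1).rename("median CD4->RTM (μm)"))

    counts = pd.DataFrame({g: {"proximal": v[0], "distal": v[1]} for g, v in sorted(prox_counts.items())})
    roe = compute_roe(counts)
    roe.to_csv(out / "proximal_roe.csv")
    print("proximal/distal Ro/e:")
    print(roe.round(3))

    contrast = pd.concat(contrasts).groupby("channel")["z_diff"].mean().round(3)
    contrast.to_csv(out / "activation_contrast.csv")
    print("mean proximal-distal z-contrast (activation channels):")
    print(contrast)


if __name__ == "__main__":
    main()
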