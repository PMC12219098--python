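"""Ro/e tissue-distribution of phenotypes across the R/NR groups.

Finding on the default cohort: fibroblasts are enriched in NR (Ro/e > 1)
and C1QC+ RTM / CD4+ T colocalized mass shifts toward R, mirroring the
planted design. Writes results/roe_phenotypes.csv (counts mode) and
results/roe_phenotypes_frequency.csv (per-ROI frequency mode).
"""

from pathlib import Path

from spatialtme import read_cell_table, roe_from_cellmaps

ROOT = Path(__file__).resolve().parents[1]


def main():
    cells = ROOT / "scratch" / "cohort" / "cells.csv"
    if not cells.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cellmaps = read_cell_table(cells)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for mode in ("counts", "frequency"):
        roe = roe_from_cellmaps(cellmaps, input=mode)
        suffix = "" if mode == "counts" else "_frequency"
        roe.to_csv(out / f"roe_phenotypes{suffix}.csv")
        print(f"--- Ro/e ({mode}) ---")
        print(roe.round(3))


if __name__ == "__main__":
    main()
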