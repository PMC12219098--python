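# spatialtme

Downstream spatial-topology analysis for segmented multiplexed-imaging data
(imaging mass cytometry and similar platforms) of the tumor
microenvironment. Given per-ROI cell tables (coordinates in μm, phenotype
labels, sample/group metadata) and optional cells×channels marker
intensities, the package quantifies how tumor, immune and stromal cells are
arranged relative to each other — the questions that matter when comparing
immunotherapy responders (R) and non-responders (NR): do C1QC+ resident
tissue macrophages (RTMs) and CD4+ T cells colocalize, and do fibroblasts
physically stand between them?

## What it computes

- **Ro/e enrichment** — for a cell-type × group count table `O`, the ratio
  `Ro/e[i,j] = O[i,j] / E[i,j]` with the chi-square expectation
  `E[i,j] = (Σ_j O)·(Σ_i O) / Σ O`; values above 1 mean the type is enriched
  in that group.
- **Cellular neighborhoods (CNs)** — each cell's window is itself plus its
  20 nearest neighbors; window composition vectors pooled cohort-wide are
  k-means-clustered into CNs, with an inertia sweep over k ∈ {5, 10, 15, 20}.
- **Pairwise cell–cell interactions (PCIs)** — for an ordered pair (A, B),
  the mean count of B among A-cells' kNN-graph neighbors, tested against a
  within-ROI phenotype-label permutation null (attraction and avoidance
  p-values, group log2 fold changes).
- **Distance / proximal–distal analysis** — per-cell Euclidean distance from
  each CD4+ T cell to its nearest C1QC+ RTM; cells are *proximal* below
  50 μm; activation-marker contrasts (z-score scale) between proximal and
  distal cells.
- **Fibroblast barrier score** — on the 5-NN spatial graph, the fraction of
  each CD4+ T cell's shortest paths to its tied-nearest RTMs whose interior
  contains an RTM-adjacent fibroblast (a fibroblast sharing a graph edge
  with an RTM), averaged over CD4 cells per image. A CD4 cell with
  fibroblasts on three of four tied-nearest paths scores 3/4.
- **ROI similarity and channel importance** — ROIs embedded as per-channel
  summary vectors; pairwise cosine similarity `cos(a,b) = a·b / (|a||b|)`
  with within/between-group block means; channel importance as the drop in
  cross-validated group-classification accuracy when a channel's feature
  block is shuffled across held-out ROIs (3 scrambles × 5 stratified folds,
  L2-regularized linear classifier).
- **Synthetic cohorts** — a Thomas-process generator that plants the
  responder/non-responder spatial signature (shared RTM/CD4 cluster parents
  in R, fibroblast rings around RTM clusters in NR, proximity-boosted
  activation markers) with full ground-truth bookkeeping, so every statistic
  above is testable against known truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py          # 20 ROIs, ~1500 cells each
python analysis/06_barrier.py
python analysis/05_distances.py
```

prints, on the default seed:

```
mean image barrier score by group:
NR    0.220
R     0.024
NR / R ratio: 9.2x

median CD4->RTM (μm):  NR 68.7   R 21.2
proximal/distal Ro/e:
             NR      R
proximal  0.678  1.323
distal    1.384  0.614
```

Non-responder ROIs have ~9× higher fibroblast barrier scores (CD4→RTM
shortest paths routinely interrupted by RTM-adjacent fibroblasts), while
responder ROIs show 3× shorter CD4→RTM distances and an enriched proximal
CD4 fraction — the planted spatial signature, recovered by the pipeline.
The numbered scripts in `analysis/` run the remaining stages (Ro/e, CNs,
PCIs, similarity/importance) and write their tables under `results/`.

A `spatialtme` CLI exposes each stage on user-supplied CSVs
(`spatialtme simulate|roe|cn|interact|distance|barrier|similarity|importance --help`).

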