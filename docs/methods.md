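# Methods

This note documents the statistical procedures, their conventions and the
design decisions behind `spatialtme`, in the order the pipeline runs them.

## Data model

A cohort is a set of ROIs (regions of interest), each a `CellMap`: segmented
cells with continuous Cartesian coordinates in μm, a phenotype label from a
closed vocabulary, and sample/group metadata. Coordinates carry no
image-axis conventions; all distances are plain Euclidean. ROI bounds
default to the bounding box of the cells and matter only to the simulator.
Group labels are free strings — the four-group preset
(MSI_R/MSI_NR/MSS_R/MSS_NR) is documentation, not a constraint; every
statistic is group-label-agnostic. Cells are kept sorted by `cell_id`, which
is the tie-breaking order everywhere a distance tie could otherwise make a
result depend on input order.

Marker matrices are loaded as already-normalized nonnegative intensities; an
optional `arcsinh(x/5)` transform is provided as a convenience for raw data.

## Ro/e enrichment

`Ro/e = O/E` with `E[i,j] = rowsum_i × colsum_j / total` (the chi-square
expectation). The default aggregates raw cell counts per group across ROIs;
a frequency mode first converts each ROI to phenotype fractions and averages
within groups, which removes the influence of unequal per-group cellularity
(the two coincide when group totals are balanced). Ro/e is reported
descriptively; no significance test is attached.

## Cellular neighborhoods

A cell's window is itself plus its `k_nn = 20` nearest neighbors (truncated
in tiny ROIs); the profile is the window's phenotype composition. Profiles
are pooled across the entire cohort before clustering so CN identities are
comparable across samples, then partitioned by k-means (10 restarts, fixed
seed — assignments are bitwise reproducible). The inertia sweep over
k ∈ {5, 10, 15, 20} supports choosing the resolution; inertia is
non-increasing in k by construction. Clustering operates on raw composition
fractions — they are already on a common scale.

## Interaction testing

The spatial graph is the union of each cell's k nearest neighbors (symmetric;
interior cells have degree ≥ k), with Euclidean edge lengths. The PCI
statistic for the ordered pair (A, B) is the mean number of B cells among
each A cell's neighbors (k = 20 by default, matching the CN window; a total
pair-count variant is exposed). The null permutes phenotype labels within the
ROI, holding the graph and the per-label counts fixed;
`p_attraction = (1 + #{perm ≥ obs}) / (1 + n_perm)` and avoidance
analogously, so p-values live in (0, 1] and the test is exact under label
exchangeability. Pairs whose phenotype is absent are reported missing, never
zero. Group contrasts are `log2((mean_A + ε)/(mean_B + ε))` with ε = 1e-6
for stability at empty pairs; significance squares use α = 0.01 by default.
The implementation evaluates the permuted statistic by a bincount over the
directed edge list, which makes 500-permutation runs on 1500-cell ROIs take
well under a second.

## Distances and proximal/distal analysis

Distances are directed (per query cell of type A to nearest B); the default
reading is CD4 → RTM, with both directions exposed. Proximal means distance
strictly below the threshold; 50 μm is the documented default (the
whole-slide co-localization convention), configurable per study. Marker
contrasts z-score each channel across the labeled cells and report the mean
z per label and their difference; zero-variance channels yield z = 0 plus a
`degenerate` flag rather than NaNs. (Contrasting z-scored *cell-level*
expression, rather than z-scoring the two group means, is what makes the
null case come out near zero and is the heatmap convention the contrast is
meant to feed.)

## Barrier score

Built on the 5-NN union graph with Euclidean edge weights ("shortest"
retains its metric meaning; an unweighted hop mode is exposed). Per CD4+ T
cell: Dijkstra distances to all RTMs; the tied-nearest set is all RTMs
within a relative tolerance (1e-9) of the minimum; one deterministic
shortest path per tied target is reconstructed by walking back from the
target and taking, at equal-length branch points, the predecessor with the
lowest `cell_id`. A path counts as blocked when its interior contains an
RTM-adjacent fibroblast — a fibroblast sharing a graph edge with at least
one RTM (the one-hop reading of "in the vicinity of" the RTMs; a
radius-based alternative can be configured upstream by relabeling).
Endpoints never count. The per-cell score is the blocked fraction over tied
targets (`path_fraction`, the default — it reproduces the canonical 3/4
worked example) or the mean number of RTM-adjacent fibroblasts along the
paths (`count`). The image score averages scored CD4 cells; CD4 cells in a
graph component with no RTM are excluded from the mean and reported.

## Similarity and channel importance

ROIs are embedded by a pluggable scheme registry. The default
`channel_summary` scheme concatenates, per channel, {mean, sd, 10th, 50th,
90th percentile} across cells, plus the ROI's phenotype frequencies. A
trained CNN embedding is deliberately out of scope: the quantitative
procedures around the embedding (cosine formula, block means, permutation
importance with cross-validation) are the reusable content, and any
fixed-length ROI vector plugs in.

Cosine similarity follows the textbook formula; the matrix is symmetrized
and its diagonal pinned to exactly 1 to absorb floating-point noise; block
means exclude the diagonal.

Channel importance: an L2-regularized multinomial logistic classifier
(`C = 100`, i.e. weight decay 0.01) predicts the group from ROI vectors
under stratified 5-fold cross-validation (folds shrink with a warning when
the smallest group is smaller). Importance of a channel is baseline held-out
accuracy minus the mean accuracy over three independent scrambles of that
channel's *entire feature block* across the held-out ROIs — permuting the
block as a unit preserves the within-ROI coupling of the remaining channels.
The model is not refit after shuffling (standard permutation importance);
an identity permutation provably contributes zero.

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline targets:
1 mm² ROIs, 25 samples × 2 ROIs in the four-group preset (8/8/4/5 samples),
or the two-group R/NR preset (5 samples × 2 ROIs per group) used by the
validation suite; ~1500 cells per ROI.

- **Backgrounds**: homogeneous Poisson per phenotype (tumor 600/mm², other
  200, fibroblast 100, CD8 100, B 80, CD4 50, RTM 20) — densities chosen to
  give a tumor-dominated ~1500-cell ROI with all core types represented.
- **Colocalization**: RTMs and CD4 T cells are Thomas cluster processes
  (10 RTM parents × Poisson(20) offspring at σ = 8 μm; 12 CD4 parents ×
  Poisson(15) at σ = 20 μm). With probability `p_share` (R: 0.8, NR: 0.15) a
  CD4 parent is placed at a random RTM parent, which is the planted
  attraction mechanism — the effect size is interpretable through the
  dispersions.
- **Barriers**: with probability `p_barrier` (R: 0.1, NR: 0.8) an RTM parent
  is encircled by a fibroblast arc at radius 25 μm covering 90% of the
  circle (≈22 cells, ~7 μm spacing, 2 μm radial jitter). The RTM dispersion
  (σ = 8) keeps >99% of offspring inside the ring and the arc spacing sits
  below the typical 5-NN edge length, so paths crossing the annulus hop
  through ring cells — the geometry that makes "blocked path" ground truth
  real rather than nominal.
- **Markers**: phenotype-conditional lognormals (lineage channels at μ = 2.0
  for their own phenotype, background μ = 0.5, σ = 0.4); CD4 cells within
  `d_act = 50` μm of an RTM get +2.0 on the activation channels (CD38, CD57,
  GZMB, TNFa, PD1). `d_act` matches the proximal threshold so the planted
  activation effect and the proximal/distal split describe the same cells.
  A per-group μ-shift hook plants group-informative channels for the
  importance validation.
- **Seeding**: per-ROI streams are `SeedSequence(master_seed,
  spawn_key=(global_sample_index, roi_index))` — stable, documented and
  disjoint within and across master seeds; each ROI's realized seed state is
  recorded in the ground truth for audit.

What the generator does **not** emulate: segmentation noise and cell-size
effects, marker spillover and batch effects, tissue architecture beyond
clusters and rings (no vessels, glands or tertiary lymphoid structures), and
spatially varying background density. Passing tests therefore demonstrate
that the statistics recover the planted effects under clean point-process
assumptions, not that any particular biological cohort will show them.

## Numerical conventions

- Distance ties everywhere resolve toward the lower `cell_id` (stable sorts
  over id-ordered cells); coincident cells get a 1e-12 μm floor edge so
  sparse storage keeps the edge.
- Permutation p-values use the add-one estimator; comparisons are exact
  float comparisons (the statistics are ratios of integers with a common
  denominator, so equality is meaningful).
- Barrier tie tolerance is relative (1e-9, scaled by the path length with a
  floor of 1); path reconstruction uses the same tolerance and is guarded
  against numerical dead ends.
- Zero-variance z-scores report 0 with a flag; all-zero Ro/e rows/columns
  are an error (zero expected count) rather than a NaN.
- Validation problem sizes (20-replicate cohorts at 10 ROIs/group, 200 CSR
  ROIs at 500 permutations, 20-seed importance batches at 50 ROIs) were
  chosen so the planted effects are far from decision boundaries while the
  whole suite stays desk-scale.

## Known limitations

- The barrier score depends on the graph k and on phenotype label quality;
  mislabeling fibroblasts at RTM edges moves scores directly.
- The permutation interaction test conditions on the observed composition of
  each ROI; it does not model cross-ROI heterogeneity (no mixed-model
  pooling) and significant pairs should be aggregated per sample before
  group-level claims.
- The `channel_summary` embedding ignores spatial arrangement inside the
  ROI; two ROIs with identical composition and intensities but different
  topology embed identically. Schemes capturing topology can be registered
  by users.
- The frequency-input mode of Ro/e averages ROI frequencies within groups,
  which weights ROIs (not cells) equally; with very uneven ROI cellularity
  the two modes answer slightly different questions.
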