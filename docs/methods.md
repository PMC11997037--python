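# Methods

This note documents the models and procedures `stedge` implements, the
defaults and why, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## The analysis problem

Given a spot-lattice transcriptomics section with per-spot tissue
annotations (five compartments: normal gland, tumor, muscularis,
submucosa, lymphoid follicle; tumor spots zoned T1 innermost … T5
outermost) and, optionally, a table of segmented cell centroids with
marker status (CD44, PTN), the pipeline asks where things sit relative
to the **tumor boundary**: which marker niches and cell populations
concentrate at the leading edge, and how cell density changes from the
tumor center to the edge.

## Niche calling

A marker niche is the top quantile (default q = 0.10) of spots ranked
by the marker's expression within a scope (all spots of the section by
default; tumor-only offered because stem-cell niches are interpreted
within tumor tissue).  Membership is exactly `ceil(q·N)`; ties are
broken by ascending barcode (a stable, documented policy — the ranking
itself fixes no tie rule).  The call depends only on the expression
ranks, so it is invariant under any strictly monotone transform of the
marker vector; normalization is irrelevant here.

Overlap between niches is reported as exact inclusion–exclusion region
counts (Venn regions) and a pairwise Jaccard matrix; niche composition
is the fraction of members per tumor zone plus a non-tumor bucket.

## Gene-set scores

* **Rank-recovery AUC** (`auc_score`): per spot, genes are ranked by
  expression descending, ties broken by gene id ascending.  With window
  `W = floor(top_frac·G)` (default top_frac = 0.05, a conventional
  choice for rank-recovery scoring), the score is
  `sum over signature genes of max(W − rank, 0)`, normalized by its
  maximum (all signature genes at the very top), hence in [0, 1] and
  invariant under per-spot monotone transforms.  Population signatures
  (iCAF: Col1a1/Il11, myCAF: Pdgfrb/Acta2, TAN: Ly6g/Cd101/Cd274) are
  mapped onto spots by AUC scoring followed by the same top-quantile
  call; this signature-score mapping stands in for single-cell-to-spot
  cluster mapping, whose algorithm is not specified in the source data
  workflows this tool mirrors.
* **Module score** (`module_score`): genes are binned (default 25 bins)
  by mean expression across spots; each signature gene draws n_ctrl
  (default 50) control genes from its own bin, seeded, without
  replacement (with replacement plus a warning when a bin is smaller —
  unavoidable on compact panels; for the ~60-gene synthetic panel the
  bundled scripts use 5 bins / 10 controls).  Score = mean signature
  minus mean control expression on log1p counts-per-10k.  Raw counts
  are accepted with a warning.  The "stemness" signature is the
  five-gene panel Alcam, Aldh2, CD44, Lgr5, Prom1.

## Geometry

* **Regions**: tumor regions are connected components of
  tumor-annotated spots under the lattice adjacency (neighbors = center
  distance ≤ 1.05·pitch; interior degree 6 on hex, 4 on square).
  Components below `min_spots` (default 10, suppressing stray single
  spots) are dropped with a log entry.  A tumor spot is **boundary** if
  it has fewer in-region lattice neighbors than the interior degree —
  i.e. at least one neighbor is non-tumor or off-lattice.
* **Spot distance**: Euclidean distance from a member spot's center to
  the nearest boundary-spot center; boundary spots are exactly 0.  This
  is lattice-exact and checked verbatim against an O(n·b) brute-force
  oracle.  Note that on a hex lattice concentric "rings" are not
  circles: the center of a 4-ring hex disc is 2√3·pitch ≈ 346 µm from
  the nearest ring-4 spot, not 4·pitch.
* **Cell distance**: cells live off-lattice, so regions are rasterized
  (default 10 µm/pixel, ≤ 10% bin-width error at 50-µm shells;
  configurable, must not exceed the pitch).  The mask is the union of
  the members' lattice Voronoi cells (nearest-spot assignment clipped
  at one pitch); holes are kept by default (flag to fill).  Boundary
  pixels are mask pixels 4-adjacent to background; a cell's distance is
  the exact Euclidean distance from its pixel center to the nearest
  boundary-pixel center (`scipy.ndimage.distance_transform_edt`), 0 on
  the boundary itself.  The raster origin is anchored to the region's
  bounding box, so rigid translation of all coordinates changes no
  distance, profile or statistic.
* **Shell profiles**: half-open bins [lo, hi) of default width 50 µm
  from 0; shell areas come from the mask-pixel distance histogram, so
  areas sum to the mask area and densities `count/area` conserve the
  in-region cell count.  Cell classes are exclusive as plotted
  (CD44⁺ excludes double positives); superset semantics are a flag.
  Whether plotted profiles elsewhere pool regions or average per-region
  means is ambiguous; pooling (summing counts and areas) is the default
  here and is what `pool_profiles` implements.

## Statistics

* **Odds ratio**: OR = ad/bc per cluster (one-vs-rest), Woolf CI
  `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`, Fisher exact p, BH across
  clusters.  With any zero cell the Haldane–Anscombe 0.5 correction is
  applied to all cells and flagged (default on; with the correction
  disabled a zero cell raises rather than returning degenerate CIs).
* **Permutation tests**: all seeded, p = (1 + #more-extreme)/(1 +
  n_perm) ∈ (0, 1], directions explicit arguments.
  *Edge enrichment*: observed mean distance-to-edge of a spot set
  versus means of uniformly resampled same-size subsets of the field.
  *Proximity*: mean nearest-neighbor distance from A to B versus
  resampled A-sized sets from a scope.
  *Density trend*: Spearman ρ between shell midpoint distance and
  density.  The null re-places the observed number of cells uniformly
  over the mask — per-shell counts resampled as multinomial with
  probabilities proportional to shell areas, which is the distribution
  a literal permutation of cell positions over the region induces on
  the binned profile (permuting the observed distance multiset alone
  would leave the profile invariant, so the spatial-randomness form is
  the operative null).  Requires ≥ 4 shells.
* Type-I error of both spatial tests is verified to sit inside the
  binomial 95% band at α = 0.05 over 400 null replicates, and power is
  verified on the planted gradients (test suite).

## Synthetic generator

The generator emulates the layered ring-like architecture the pipeline
targets, with every effect planted and parameterized:

* **Lattice**: hex with offset rows (Visium-like), pitch 100 µm, spot
  diameter 50 µm; square lattice supported because its geometry oracles
  are simpler.  Coordinates in µm, x rightward, y downward; bins
  half-open.
* **Compartments**: a circular tumor (default radius 1200 µm in a
  4 × 4 mm section) split into five equal-width concentric zones
  (T1 center … T5 rim), wrapped by normal-gland, submucosa, muscularis
  and lymphoid bands; the remainder is normal gland.  Spot counts per
  compartment are free parameters of the geometry, not calibrated to
  any particular dataset.
* **Counts**: negative binomial with variance µ + µ²/k and one global
  dispersion k = 2 (a typical spot-level overdispersion; no count model
  is prescribed by the problem).  Mean of gene g at spot s:
  `base_mean(compartment, g) · f_g(d)`, with f = 1 + A·e^(−d/τ) for
  edge-high genes, 1 + A·e^(−(R−d)/τ) for center-high (R the region's
  maximum depth), 1 otherwise.  Defaults: CD44 edge-high and Lgr5
  center-high (A = 4, τ = 150 µm); CAF/TAN signature genes strongly
  rim-confined (A = 8, τ = 150 µm); Alcam/Aldh2/Prom1 flat within the
  tumor, matching their dispersed niches; a 36-gene housekeeping
  background cycling over five expression depths.
* **Cells**: per class, an inhomogeneous Poisson process over the
  rasterized tumor mask with λ(d) = λ₀ + λ₁·e^(−d/τ) cells/mm² (pixel
  counts Poisson with mean λ·pixel area, positions uniform within the
  pixel).  Defaults: CD44⁺PTN⁺ λ = 20 + 180·e^(−d/100) — the planted
  center-to-edge gradient used throughout the studies — CD44⁺
  λ = 30 + 150·e^(−d/120), and PTN⁺ flat at 80/mm² (PTN single
  positives carry no radial pattern).
* **Determinism**: identical (config, seed) gives bit-identical output;
  counts and cells use separate RNG streams derived from the master
  seed by fixed offsets, so enabling one artifact never shifts the
  other.  The generator uses the *same* distance definitions as the
  analysis modules (lattice-exact for spots, raster EDT for cells), so
  planted and recovered gradients cannot disagree about geometry.

## Study designs in the test suite and acceptance script

* The **density-gradient study** uses six elongated tumor fields
  (7 × 60 spot blocks, ≈ 0.7 × 6 mm) rather than discs.  Elongated
  fields emulate imaging fields along a tumor boundary and keep every
  50-µm shell's pooled area large; in a disc the deep shells shrink to
  a few pixels and their density estimates are pure noise.  With this
  geometry the pooled profile recovers the planted gradient with
  Spearman ρ ≤ −0.9 and trend p < 0.01 in ≥ 95% of seeds.
* The **marker-pattern study** runs 100 seeded default sections and
  checks that the CD44 niche's mean distance-to-edge is below the Lgr5
  niche's and that CD44 edge enrichment rejects at p < 0.01.
* Null calibrations run 400 replicates each with 999 permutations.

## What passing tests do and do not show

The generator plants smooth radial effects on ideal geometry: one
convex tumor per section (or clean rectangular fields), no segmentation
errors, no spot-swapping or bleed-over, no batch effects, a single
global dispersion, and compartment annotations that are exactly right.
Passing tests therefore demonstrate that the estimators and tests
recover what they are designed to recover and are calibrated under
their own nulls — not that real sections satisfy these assumptions.
On real data the annotations, segmentation quality and the choice of
ranking scope (section-wide vs tumor-only) will dominate.

## Known limitations

* Tumor regions come from annotations only; no inference of tumor
  versus stroma from expression, and no 3-D geometry.
* Cell distances are raster-quantized (half-pixel-diagonal accuracy);
  spot distances use boundary-spot centers, which can differ from the
  mask EDT by up to about one pitch on shared geometry.
* The ncRNA/mitochondrial gene filtering some workflows apply needs a
  gene-type dictionary the package does not ship; an exclusion list
  can be applied upstream instead.
* Gene symbols match case-sensitively by default (an optional
  case-insensitive flag exists for mixed human/mouse symbol styles).
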