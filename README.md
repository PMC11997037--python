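# stedge

Spatial leading-edge analysis of tumor tissue sections.

Solid tumors are not well-mixed: in colorectal cancer, spatial
transcriptomics reveals a layered, ring-like organization in which
CD44⁺ tumor cells with high stemness, inflammatory and myofibroblastic
cancer-associated fibroblasts (iCAF/myCAF-like) and pro-tumor
neutrophils concentrate at the tumor's **leading edge** — the outer rim
abutting non-tumor tissue — while Lgr5⁺ cells sit in the tumor center.
`stedge` is a library + CLI for quantifying exactly this kind of
geometry on Visium-style spot lattices and segmented-cell point clouds,
for computational biologists analysing spatial tumor data.

## What it computes

* **Marker niches** — rank all spots of a section by a marker gene's
  expression and call the top quantile (default the top 10%) as that
  marker's niche; deterministic tie policy, exact `ceil(q·N)` membership;
  Venn-style exact-region overlap counts and Jaccard matrices across
  markers; per-zone (T1–T5) niche composition.
* **Gene-set scores per spot** — a rank-recovery AUC score
  (area under the signature's recovery curve over the top fraction of
  per-spot gene ranks, in [0, 1]) and a background-corrected module
  score (mean signature expression minus expression-matched controls on
  log1p CP10k), used to map population signatures (iCAF, myCAF, TAN)
  onto spots.
* **Tumor geometry** — tumor regions as connected components of
  tumor-annotated spots on the lattice adjacency graph; boundary spots;
  lattice-exact spot distance-to-edge and rasterized Euclidean
  distance-transform cell distance-to-edge, with 0 µm at the boundary;
  50-µm shell density profiles `density(bin) = count/area` per cell
  class (CD44⁺, PTN⁺, CD44⁺PTN⁺).
* **Enrichment statistics** — odds ratios
  `OR = ad/bc` with Haldane–Anscombe correction, Woolf CIs and Fisher
  exact p; seeded permutation tests for edge proximity of a spot set,
  set-to-set proximity, and the center-to-edge density trend (Spearman ρ
  of density vs shell distance against a complete-spatial-randomness
  null); Benjamini–Hochberg adjustment.
* **Synthetic sections** — a fully parameterized generator (hex or
  square lattice, five tissue compartments, concentric tumor zones,
  negative-binomial counts with planted radial gradients, inhomogeneous
  Poisson cell point clouds with intensity λ(d) = λ₀ + λ₁·e^(−d/τ))
  providing known ground truth for every downstream stage.

## Worked example

```python
from stedge import (
    SyntheticConfig, generate_section, build_adjacency, extract_tumor_regions,
    spot_edge_distance, call_marker_niches, edge_enrichment_test,
)

cfg = SyntheticConfig(seed=1)                      # layered ring-like section
grid, comp, counts, cells = generate_section(cfg)
region = extract_tumor_regions(comp, build_adjacency(grid), min_spots=1)[0]
field = spot_edge_distance(region)                 # 0 um = tumor boundary
dist = field.as_series()

for marker in ("CD44", "Lgr5"):
    niche = call_marker_niches(counts, marker, comp=comp, q=0.10)
    in_tumor = [b for b in niche.member_barcodes if b in dist.index]
    res = edge_enrichment_test(in_tumor, field, n_perm=999, seed=1, direction="less")
    print(f"{marker}: {len(niche)} niche spots, "
          f"mean distance to edge {dist[in_tumor].mean():.0f} um, "
          f"edge-enrichment p = {res.p_value:.3g}")
```

prints

```
CD44: 182 niche spots, mean distance to edge 187 um, edge-enrichment p = 0.001
Lgr5: 182 niche spots, mean distance to edge 414 um, edge-enrichment p = 1
```

The section has 1817 spots, so each top-10% niche holds exactly
`ceil(0.1 · 1817) = 182` spots.  The planted edge-high CD44 gradient puts
the CD44 niche ~187 µm from the boundary on average — significantly
closer than random spot sets of the same size (p = 1/1000, the smallest
value attainable with 999 permutations) — while the center-high Lgr5
niche sits ~414 µm deep and shows no edge enrichment.

## Command line

Each stage is a subcommand over one YAML config, so real annotated data
can replace the simulator at any boundary:

```sh
stedge -c config.yaml simulate        # synthetic section -> run dir
stedge -c config.yaml call-niches     # niches.tsv, overlap.json, scores.tsv
stedge -c config.yaml map-populations # populations.tsv (signature mapping)
stedge -c config.yaml edge-distance   # distances.tsv, regions.geojson
stedge -c config.yaml profile         # profile.csv (50-um shell densities)
stedge -c config.yaml enrich          # stats.json (permutation tests)
stedge -c config.yaml report          # human-readable summary
```

Reruns with the same config and seeds are byte-identical;
`run_manifest.json` records config hashes, versions and seeds.

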