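"""Synthetic sections with a layered ring-like tumor architecture.

Every downstream stage of the pipeline is exercised against sections
produced here, with planted, fully parameterized spatial effects: a spot
lattice (Visium-like hex by default), five tissue compartments arranged
as concentric bands around a circular tumor, negative-binomial counts
whose means carry radial gradients (edge-high CD44, center-high Lgr5,
rim-confined CAF/TAN signatures), and marker-positive cell point clouds
from inhomogeneous Poisson processes whose intensity decays with distance
to the tumor boundary.

Distances used by the generator are the ones the analysis modules
compute (lattice-exact for spots, rasterized EDT for cells), so planted
gradients and recovered gradients share a single distance definition.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SyntheticConfig
from .geometry import (
    DEFAULT_PIXEL_SIZE_UM,
    TumorRegion,
    build_adjacency,
    cell_edge_distance,
    extract_tumor_regions,
    spot_edge_distance,
)
from .types import CLASS_FLAGS, CellTable, CompartmentMap, CountMatrix, SpotGrid

logger = logging.getLogger(__name__)


def generate_spot_grid(config: SyntheticConfig) -> SpotGrid:
    """Lattice of spot centers covering the section extent.

    Square: rows and columns at pitch spacing.  Hex: offset rows at
    pitch * sqrt(3)/2 vertical spacing, odd rows shifted half a pitch, so
    every interior spot has six equidistant neighbors.
    """
    w, h = config.section_extent_um
    p = config.pitch_um
    if w < p or h < p:
        raise ValueError("degenerate section: extent smaller than one pitch")
    half = p / 2.0
    row_spacing = p if config.lattice == "square" else p * np.sqrt(3) / 2.0
    ys = np.arange(half, h - half + 1e-9, row_spacing)
    rows, cols, xs_all, ys_all = [], [], [], []
    for r, y in enumerate(ys):
        offset = half if (config.lattice == "hex" and r % 2 == 1) else 0.0
        xs = np.arange(half + offset, w - half + 1e-9, p)
        rows.extend([r] * len(xs))
        cols.extend(range(len(xs)))
        xs_all.extend(xs)
        ys_all.extend([y] * len(xs))
    n = len(xs_all)
    if n == 0:
        raise ValueError("degenerate section: no spots fit the extent")
    return SpotGrid(
        barcodes=np.array([f"SP{i:05d}" for i in range(n)], dtype=object),
        array_row=np.array(rows, dtype=int),
        array_col=np.array(cols, dtype=int),
        x_um=np.array(xs_all, dtype=float),
        y_um=np.array(ys_all, dtype=float),
        lattice=config.lattice,
        pitch_um=p,
        spot_diameter_um=config.spot_diameter_um,
    )


def assign_compartments(grid: SpotGrid, config: SyntheticConfig) -> CompartmentMap:
    """Radial compartment layout: tumor disc, zones T1-T5, outer bands.

    Spots within the tumor radius are tumor, zoned by ``zone_edges_um``
    (T1 innermost).  Successive outer bands follow
    ``compartment_band_widths_um`` in mapping order; everything beyond is
    normal_gland.
    """
    cx, cy = config.tumor_center_um
    w, h = config.section_extent_um
    R = config.tumor_radius_um
    if cx - R < 0 or cy - R < 0 or cx + R > w or cy + R > h:
        raise ValueError("tumor disc does not fit inside the section extent")
    r = np.hypot(grid.x_um - cx, grid.y_um - cy)
    comp = np.full(grid.n_spots, "normal_gland", dtype=object)
    zone = np.full(grid.n_spots, None, dtype=object)
    in_tumor = r <= R
    comp[in_tumor] = "tumor"
    zidx = np.searchsorted(np.asarray(config.zone_edges_um, dtype=float), r[in_tumor], side="right")
    zone[in_tumor] = np.array([f"T{i + 1}" for i in zidx], dtype=object)
    edges = R + np.cumsum([config.compartment_band_widths_um[k] for k in config.compartment_band_widths_um])
    names = list(config.compartment_band_widths_um)
    lo = R
    for name, hi in zip(names, edges):
        band = (r > lo) & (r <= hi)
        comp[band] = name
        lo = hi
    frame = pd.DataFrame(
        {"compartment": comp, "zone": zone}, index=pd.Index(grid.barcodes, name="barcode")
    )
    return CompartmentMap(frame)


def _tumor_edge_distances(
    grid: SpotGrid, comp: CompartmentMap, min_spots: int = 1
) -> Tuple[np.ndarray, np.ndarray, list]:
    """Per-spot (distance d, region max-depth R) for tumor spots; NaN elsewhere."""
    adj = build_adjacency(grid)
    regions = extract_tumor_regions(comp, adj, min_spots=min_spots)
    d = np.full(grid.n_spots, np.nan)
    depth = np.full(grid.n_spots, np.nan)
    for region in regions:
        f = spot_edge_distance(region)
        d[region.member_idx] = f.distance_um
        depth[region.member_idx] = f.distance_um.max()
    return d, depth, regions


def simulate_counts(
    grid: SpotGrid, comp: CompartmentMap, config: SyntheticConfig
) -> CountMatrix:
    """Negative-binomial counts with planted radial mean gradients.

    The mean of gene g at spot s is base_mean(compartment(s), g) times a
    radial factor f_g(d): 1 + A * exp(-d/tau) for edge-high genes,
    1 + A * exp(-(R - d)/tau) for center-high genes (R the region's
    maximum in-tumor distance), and 1 for flat genes and all non-tumor
    spots.  Variance follows mu + mu^2 / k with one global dispersion k.
    """
    comp.check_covers(grid)
    genes = config.genes
    comp_series = comp.compartment_of().reindex(grid.barcodes)
    mu = np.empty((len(genes), grid.n_spots), dtype=float)
    for ci, c in enumerate(comp_series.to_numpy()):
        means = config.nb_mean[c]
        mu[:, ci] = [means[g] for g in genes]
    if config.gradient_genes:
        d, depth, _ = _tumor_edge_distances(grid, comp)
        in_tumor = ~np.isnan(d)
        for gi, g in enumerate(genes):
            spec = config.gradient_genes.get(g)
            if spec is None or spec.direction == "flat" or spec.amplitude == 0:
                continue
            if spec.direction == "edge_high":
                f = 1.0 + spec.amplitude * np.exp(-d[in_tumor] / spec.decay_tau_um)
            else:  # center_high
                f = 1.0 + spec.amplitude * np.exp(
                    -(depth[in_tumor] - d[in_tumor]) / spec.decay_tau_um
                )
            mu[gi, in_tumor] *= f
    if not np.all(mu > 0):
        raise ValueError("nonpositive negative-binomial mean")
    k = config.nb_dispersion
    rng = config.counts_rng()
    counts = rng.negative_binomial(k, k / (k + mu))
    return CountMatrix(
        gene_ids=np.array(genes, dtype=object),
        barcodes=grid.barcodes,
        values=sp.csr_matrix(counts),
    )


def simulate_cells(
    comp: CompartmentMap,
    grid: SpotGrid,
    config: SyntheticConfig,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> CellTable:
    """Marker-positive cells from inhomogeneous Poisson point processes.

    For each cell class, intensity lambda(d) = l0 + l1 * exp(-d/tau)
    cells/mm² over the rasterized tumor mask, d the pixel's distance to
    the boundary.  Pixel counts are Poisson with mean lambda * pixel
    area; positions are uniform within the pixel, so the expected total
    equals the intensity integrated over the tumor area.
    """
    comp.check_covers(grid)
    tumor_bcs = comp.barcodes_for("tumor")
    if tumor_bcs.size == 0:
        raise ValueError("empty tumor mask: no tumor-labeled spots")
    adj = build_adjacency(grid)
    regions = extract_tumor_regions(comp, adj, min_spots=1, pixel_size_um=pixel_size_um)
    rng = config.cells_rng()
    px = pixel_size_um
    apx_mm2 = (px / 1000.0) ** 2
    records = []
    for region in regions:
        mask = region.mask
        edt = region.pixel_edge_distance_um
        iy, ix = np.nonzero(mask)
        d = edt[iy, ix]
        x0, y0 = region.origin_um
        cx = x0 + (ix + 0.5) * px
        cy = y0 + (iy + 0.5) * px
        for cls in sorted(config.cell_classes):
            spec = config.cell_classes[cls]
            lam = spec.lambda0_per_mm2 + spec.lambda1_per_mm2 * np.exp(
                -d / spec.decay_tau_um
            )
            n_pix = rng.poisson(lam * apx_mm2)
            total = int(n_pix.sum())
            if total == 0:
                continue
            reps = np.repeat(np.arange(len(d)), n_pix)
            jitter = rng.uniform(-px / 2.0, px / 2.0, size=(total, 2))
            xs = cx[reps] + jitter[:, 0]
            ys = cy[reps] + jitter[:, 1]
            cd44, ptn = CLASS_FLAGS[cls]
            records.append(
                pd.DataFrame(
                    {
                        "x_um": xs,
                        "y_um": ys,
                        "CD44_pos": cd44,
                        "PTN_pos": ptn,
                    }
                )
            )
    if records:
        frame = pd.concat(records, ignore_index=True)
    else:
        frame = pd.DataFrame(
            {
                "x_um": pd.Series(dtype=float),
                "y_um": pd.Series(dtype=float),
                "CD44_pos": pd.Series(dtype=bool),
                "PTN_pos": pd.Series(dtype=bool),
            }
        )
    frame.insert(0, "cell_id", [f"C{i:06d}" for i in range(len(frame))])
    return CellTable(frame)


def generate_section(config: SyntheticConfig, with_cells: bool = True):
    """Convenience: (grid, compartments, counts, cells) for one config."""
    grid = generate_spot_grid(config)
    comp = assign_compartments(grid, config)
    counts = simulate_counts(grid, comp, config)
    cells = simulate_cells(comp, grid, config) if with_cells else None
    return grid, comp, counts, cells
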