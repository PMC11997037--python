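"""Tumor regions, boundaries, distance-to-edge fields and shell profiles.

The geometric core of the leading-edge analysis.  Tumor regions are
connected components of tumor-labeled spots under the lattice adjacency;
the boundary is the set of tumor spots with at least one neighbor that is
non-tumor or off-lattice.  Two distance definitions are used on purpose:

* spot-level distance is the exact Euclidean distance from a member
  spot's center to the nearest boundary-spot center (lattice-exact,
  oracle-checkable);
* cell-level distance is read off a rasterized mask: the exact Euclidean
  distance from the cell's pixel center to the nearest boundary-pixel
  center (boundary pixels are mask pixels 4-adjacent to background or to
  the raster border).

Both fields are 0 on the boundary itself, matching the convention that
0 μm marks the tumor edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import CELL_CLASSES, CellTable, CompartmentMap, SpotGrid

logger = logging.getLogger(__name__)

#: default raster resolution for region masks (μm per pixel)
DEFAULT_PIXEL_SIZE_UM = 10.0

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class AdjacencyGraph:
    """Spot adjacency under the lattice metric (symmetric, no self-loops)."""

    grid: SpotGrid
    neighbors: tuple  # tuple of np.ndarray of neighbor indices per spot

    @property
    def interior_degree(self) -> int:
        return 6 if self.grid.lattice == "hex" else 4

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def pairs(self) -> np.ndarray:
        """(m, 2) array of undirected edges i < j."""
        out = [
            (i, j) for i, nbs in enumerate(self.neighbors) for j in nbs if i < j
        ]
        return np.array(out, dtype=int).reshape(-1, 2)


def build_adjacency(grid: SpotGrid) -> AdjacencyGraph:
    """Neighbors are spot pairs with center distance <= 1.05 * pitch.

    On a hex lattice this yields the six nearest spots; on a square
    lattice the four axis-aligned ones (diagonals sit at ~1.41 * pitch).
    Isolated spots are allowed (degree 0).
    """
    tree = cKDTree(grid.coords)
    pairs = tree.query_pairs(r=1.05 * grid.pitch_um, output_type="ndarray")
    neighbors: list = [[] for _ in range(grid.n_spots)]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    return AdjacencyGraph(
        grid=grid,
        neighbors=tuple(np.array(sorted(nb), dtype=int) for nb in neighbors),
    )


@dataclass(frozen=True)
class TumorRegion:
    """One connected component of tumor spots, with a rasterized mask.

    The mask is the union of the members' lattice cells (the Voronoi
    cells of the spot lattice, clipped at one pitch), rasterized at
    ``pixel_size_um``; ``origin_um`` is the μm coordinate of the top-left
    pixel corner, so pixel (iy, ix) has center
    origin + (ix + 0.5, iy + 0.5) * pixel_size.
    """

    region_id: str
    grid: SpotGrid
    member_idx: np.ndarray
    boundary_idx: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if not set(self.boundary_idx.tolist()) <= set(self.member_idx.tolist()):
            raise ValueError("boundary spots must be a subset of members")
        if self.member_idx.size == 0:
            raise ValueError("empty tumor region")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.pixel_size_um > self.grid.pitch_um:
            raise ValueError("pixel size > pitch: mask too coarse")

    @property
    def member_barcodes(self) -> np.ndarray:
        return self.grid.barcodes[self.member_idx]

    @property
    def boundary_barcodes(self) -> np.ndarray:
        return self.grid.barcodes[self.boundary_idx]

    @property
    def n_spots(self) -> int:
        return len(self.member_idx)

    @cached_property
    def _raster(self) -> dict:
        grid = self.grid
        px = self.pixel_size_um
        coords = grid.coords
        mem = coords[self.member_idx]
        # origin anchored to the region (not a global pixel grid) so a rigid
        # translation of the section translates the raster with it
        pad = grid.pitch_um
        x0 = mem[:, 0].min() - pad
        y0 = mem[:, 1].min() - pad
        nx = int(np.ceil((mem[:, 0].max() + pad - x0) / px))
        ny = int(np.ceil((mem[:, 1].max() + pad - y0) / px))
        xs = x0 + (np.arange(nx) + 0.5) * px
        ys = y0 + (np.arange(ny) + 0.5) * px
        gx, gy = np.meshgrid(xs, ys)
        pix = np.column_stack([gx.ravel(), gy.ravel()])
        tree = cKDTree(coords)
        dist, nearest = tree.query(pix, k=1)
        is_member = np.zeros(grid.n_spots, dtype=bool)
        is_member[self.member_idx] = True
        mask = (is_member[nearest] & (dist <= grid.pitch_um)).reshape(ny, nx)
        if self.fill_holes:
            mask = ndi.binary_fill_holes(mask)
        if not mask.any():
            raise ValueError("rasterized mask has zero area")
        interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
        boundary_pix = mask & ~interior
        # exact Euclidean distance (μm) to the nearest boundary-pixel center
        edt = ndi.distance_transform_edt(~boundary_pix) * px
        return {"origin": (x0, y0), "mask": mask, "edt": edt}

    @property
    def origin_um(self) -> tuple:
        return self._raster["origin"]

    @property
    def mask(self) -> np.ndarray:
        return self._raster["mask"]

    @property
    def pixel_edge_distance_um(self) -> np.ndarray:
        """Distance-to-boundary raster (μm); meaningful on mask pixels."""
        return self._raster["edt"]

    @property
    def mask_area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_um / 1000.0) ** 2

    def boundary_polygon(self):
        """Shapely (multi)polygon of the union of member lattice cells."""
        from shapely.geometry import Point
        from shapely.ops import unary_union

        # circumradius of the lattice cell: pitch/sqrt(3) (hex), pitch/sqrt(2) (square)
        r = self.grid.pitch_um / (np.sqrt(3) if self.grid.lattice == "hex" else np.sqrt(2))
        cells = [
            Point(x, y).buffer(r, quad_segs=8)
            for x, y in self.grid.coords[self.member_idx]
        ]
        return unary_union(cells)


@dataclass(frozen=True)
class EdgeDistanceField:
    """Non-negative distance (μm) of spots or cells to the tumor boundary."""

    subject: str  # 'spots' | 'cells'
    ids: np.ndarray
    distance_um: np.ndarray
    region_id: str

    def __post_init__(self) -> None:
        if self.subject not in ("spots", "cells"):
            raise ValueError("subject must be 'spots' or 'cells'")
        d = np.asarray(self.distance_um, dtype=float)
        if d.shape != (len(self.ids),):
            raise ValueError("ids/distances length mismatch")
        if d.size and d.min() < 0:
            raise ValueError("negative distance")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.ids,
                "region_id": self.region_id,
                "distance_um": self.distance_um,
            }
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.distance_um, index=self.ids, name="distance_um")


@dataclass(frozen=True)
class DensityProfile:
    """Shell-binned cell densities from the boundary (bin 0 at the edge).

    Half-open bins [lo, hi) of fixed width from 0 μm.  Densities are
    count/area exactly; shell areas come from mask-pixel counts whose
    edge distance falls in the bin, so areas sum to the mask area and
    counts sum to the number of in-region cells of each class.
    """

    bin_edges_um: np.ndarray
    area_mm2: np.ndarray
    counts: dict  # class -> np.ndarray of per-bin counts
    region_ids: tuple

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_um, dtype=float)
        if edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be ascending")
        nb = edges.size - 1
        if np.asarray(self.area_mm2).shape != (nb,):
            raise ValueError("area array does not match bins")
        for cls, c in self.counts.items():
            if np.asarray(c).shape != (nb,):
                raise ValueError(f"count array for {cls!r} does not match bins")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_um) - 1

    @property
    def midpoints_um(self) -> np.ndarray:
        e = self.bin_edges_um
        return (e[:-1] + e[1:]) / 2.0

    def density(self, cls: str) -> np.ndarray:
        """Cells per mm² in each shell."""
        area = np.asarray(self.area_mm2, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(area > 0, self.counts[cls] / area, 0.0)
        return d

    def total(self, cls: str) -> int:
        return int(np.sum(self.counts[cls]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        e = self.bin_edges_um
        for cls, c in self.counts.items():
            dens = self.density(cls)
            for b in range(self.n_bins):
                rows.append(
                    {
                        "class": cls,
                        "bin_lo": e[b],
                        "bin_hi": e[b + 1],
                        "count": int(c[b]),
                        "area_mm2": self.area_mm2[b],
                        "density_per_mm2": dens[b],
                    }
                )
        return pd.DataFrame(rows)


def extract_tumor_regions(
    comp: CompartmentMap,
    adj: AdjacencyGraph,
    min_spots: int = 10,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    fill_holes: bool = False,
) -> list:
    """Connected components of tumor spots, largest first.

    Components smaller than ``min_spots`` are dropped (logged).  Raises
    if no region survives.
    """
    grid = adj.grid
    comp.check_covers(grid)
    comp_series = comp.compartment_of().reindex(grid.barcodes)
    is_tumor = (comp_series == "tumor").to_numpy()
    tumor_idx = np.flatnonzero(is_tumor)
    if tumor_idx.size == 0:
        raise ValueError("no tumor region: no tumor-labeled spots")
    # connected components of the tumor-restricted adjacency
    pos = -np.ones(grid.n_spots, dtype=int)
    pos[tumor_idx] = np.arange(tumor_idx.size)
    rows, cols = [], []
    for i in tumor_idx:
        for j in adj.neighbors[i]:
            if is_tumor[j]:
                rows.append(pos[i])
                cols.append(pos[j])
    g = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(tumor_idx.size, tumor_idx.size)
    )
    n_comp, labels = connected_components(g, directed=False)
    regions = []
    interior_deg = adj.interior_degree
    for lab in range(n_comp):
        members = tumor_idx[labels == lab]
        if members.size < min_spots:
            logger.info(
                "dropping tumor component of %d spot(s) < min_spots=%d",
                members.size,
                min_spots,
            )
            continue
        member_set = set(members.tolist())
        boundary = np.array(
            [
                i
                for i in members
                if sum(1 for j in adj.neighbors[i] if j in member_set) < interior_deg
            ],
            dtype=int,
        )
        regions.append((members, boundary))
    if not regions:
        raise ValueError("no tumor region after min_spots filtering")
    regions.sort(key=lambda mb: (-mb[0].size, mb[0].min()))
    return [
        TumorRegion(
            region_id=f"R{k}",
            grid=grid,
            member_idx=members,
            boundary_idx=boundary,
            pixel_size_um=pixel_size_um,
            fill_holes=fill_holes,
        )
        for k, (members, boundary) in enumerate(regions)
    ]


def spot_edge_distance(region: TumorRegion, grid: Optional[SpotGrid] = None) -> EdgeDistanceField:
    """Distance of each member spot to the nearest boundary-spot center.

    Boundary spots are exactly 0.  Lattice-exact (no rasterization).
    """
    grid = grid if grid is not None else region.grid
    mem = grid.coords[region.member_idx]
    bnd = grid.coords[region.boundary_idx]
    tree = cKDTree(bnd)
    dist, _ = tree.query(mem, k=1)
    is_boundary = np.isin(region.member_idx, region.boundary_idx)
    dist[is_boundary] = 0.0
    return EdgeDistanceField(
        subject="spots",
        ids=grid.barcodes[region.member_idx],
        distance_um=dist,
        region_id=region.region_id,
    )


def cell_edge_distance(region: TumorRegion, cells: CellTable) -> EdgeDistanceField:
    """Edge distance of the cells that fall inside the region's mask.

    Each cell takes the distance raster value of its pixel; cells outside
    the mask are excluded and counted in the log.
    """
    px = region.pixel_size_um
    x0, y0 = region.origin_um
    mask = region.mask
    edt = region.pixel_edge_distance_um
    coords = cells.coords
    ix = np.floor((coords[:, 0] - x0) / px).astype(int)
    iy = np.floor((coords[:, 1] - y0) / px).astype(int)
    ny, nx = mask.shape
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    keep = inside.copy()
    keep[inside] = mask[iy[inside], ix[inside]]
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "region %s: excluded %d cell(s) outside the mask", region.region_id, n_excluded
        )
    dist = edt[iy[keep], ix[keep]]
    ids = cells.frame["cell_id"].to_numpy(dtype=object)[keep]
    return EdgeDistanceField(
        subject="cells", ids=ids, distance_um=dist, region_id=region.region_id
    )


def shell_profile(
    field: EdgeDistanceField,
    region: TumorRegion,
    cells: CellTable,
    bin_width_um: float = 50.0,
    classes: Sequence[str] = CELL_CLASSES,
    exclusive: bool = True,
) -> DensityProfile:
    """Half-open 50-μm shells from the boundary inward, per cell class.

    Shell areas come from the mask-pixel distance histogram; by default
    classes are exclusive as plotted (CD44+ excludes double positives).
    """
    if field.subject != "cells":
        raise ValueError("shell_profile expects a cell distance field")
    if not bin_width_um > 0:
        raise ValueError("bin_width_um must be positive")
    pix_d = region.pixel_edge_distance_um[region.mask]
    if pix_d.size == 0:
        raise ValueError("empty region mask")
    n_bins = max(1, int(np.floor(pix_d.max() / bin_width_um)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    apx = (region.pixel_size_um / 1000.0) ** 2
    area = np.histogram(pix_d, bins=edges)[0] * apx
    id_to_row = pd.Index(cells.frame["cell_id"])
    rows = id_to_row.get_indexer(field.ids)
    counts = {}
    for cls in classes:
        m = cells.class_mask(cls, exclusive=exclusive)[rows]
        counts[cls] = np.histogram(field.distance_um[m], bins=edges)[0]
    return DensityProfile(
        bin_edges_um=edges, area_mm2=area, counts=counts, region_ids=(region.region_id,)
    )


def pool_profiles(profiles: Sequence[DensityProfile]) -> DensityProfile:
    """Pool counts and shell areas across regions sharing a bin width."""
    if not profiles:
        raise ValueError("no profiles to pool")
    width = profiles[0].bin_edges_um[1] - profiles[0].bin_edges_um[0]
    for p in profiles:
        w = p.bin_edges_um[1] - p.bin_edges_um[0]
        if not np.isclose(w, width):
            raise ValueError("profiles have differing bin widths")
    n_bins = max(p.n_bins for p in profiles)
    edges = np.arange(n_bins + 1, dtype=float) * width
    area = np.zeros(n_bins)
    classes = list(profiles[0].counts)
    counts = {cls: np.zeros(n_bins, dtype=int) for cls in classes}
    for p in profiles:
        area[: p.n_bins] += p.area_mm2
        for cls in classes:
            counts[cls][: p.n_bins] += p.counts[cls]
    region_ids = tuple(r for p in profiles for r in p.region_ids)
    return DensityProfile(
        bin_edges_um=edges, area_mm2=area, counts=counts, region_ids=region_ids
    )
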