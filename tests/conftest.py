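import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stedge import (
    CellTable,
    CompartmentMap,
    CountMatrix,
    SpotGrid,
    SyntheticConfig,
    assign_compartments,
    build_adjacency,
    generate_spot_grid,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Smaller disc section for fast unit tests (same architecture)."""
    return SyntheticConfig(
        seed=7,
        section_extent_um=(2400.0, 2400.0),
        tumor_center_um=(1200.0, 1200.0),
        tumor_radius_um=700.0,
        zone_edges_um=(140.0, 280.0, 420.0, 560.0),
        compartment_band_widths_um={
            "normal_gland": 200.0,
            "submucosa": 200.0,
            "muscularis": 150.0,
            "lymphoid_follicle": 100.0,
        },
    )


@pytest.fixture(scope="session")
def small_section(small_config):
    from stedge import generate_section

    grid, comp, counts, cells = generate_section(small_config)
    return {"config": small_config, "grid": grid, "comp": comp, "counts": counts, "cells": cells}


def square_grid(n_rows, n_cols, pitch=100.0, origin=(50.0, 50.0)):
    """Plain square lattice for constructed geometry fixtures."""
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    return SpotGrid(
        barcodes=np.array([f"SP{i:05d}" for i in range(rows.size)], dtype=object),
        array_row=rows,
        array_col=cols,
        x_um=origin[0] + cols * pitch,
        y_um=origin[1] + rows * pitch,
        lattice="square",
        pitch_um=pitch,
        spot_diameter_um=pitch / 2,
    )


def compartment_map_from_labels(grid, labels, zones=None):
    frame = pd.DataFrame(
        {"compartment": labels, "zone": zones if zones is not None else pd.NA},
        index=pd.Index(grid.barcodes, name="barcode"),
    )
    return CompartmentMap(frame)


def rect_tumor_map(grid, row_lo, row_hi, col_lo, col_hi, background="normal_gland"):
    """Rectangular tumor block [row_lo, row_hi) x [col_lo, col_hi)."""
    in_rect = (
        (grid.array_row >= row_lo)
        & (grid.array_row < row_hi)
        & (grid.array_col >= col_lo)
        & (grid.array_col < col_hi)
    )
    labels = np.where(in_rect, "tumor", background).astype(object)
    return compartment_map_from_labels(grid, labels)


def counts_from_dense(dense, gene_ids=None, barcodes=None):
    dense = np.asarray(dense)
    g, n = dense.shape
    return CountMatrix(
        gene_ids=np.array(gene_ids if gene_ids is not None else [f"g{i:03d}" for i in range(g)], dtype=object),
        barcodes=np.array(barcodes if barcodes is not None else [f"SP{i:05d}" for i in range(n)], dtype=object),
        values=sp.csr_matrix(dense),
    )


def cells_from_coords(coords, cd44=None, ptn=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = len(coords)
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"C{i:06d}" for i in range(n)],
                "x_um": coords[:, 0],
                "y_um": coords[:, 1],
                "CD44_pos": np.zeros(n, bool) if cd44 is None else np.asarray(cd44, bool),
                "PTN_pos": np.zeros(n, bool) if ptn is None else np.asarray(ptn, bool),
            }
        )
    )
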