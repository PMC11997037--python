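"""Readers and writers for the plain-text formats the pipeline touches.

Sections are stored Visium-style: ``tissue_positions.csv`` (barcode,
in_tissue, array_row, array_col, pxl_x, pxl_y), a Matrix Market
``matrix.mtx`` (genes x spots, 1-based coordinates) with ``features.tsv``
and ``barcodes.tsv``, plus ``annotations.tsv`` (barcode, compartment,
zone), ``cells.csv`` (cell_id, x_um, y_um, class) and a
``scalefactors.json`` sidecar carrying the μm-per-pixel scale and the
lattice parameters — μm coordinates are authoritative, pixel columns are
stored but unused.  Readers validate strictly and reject rather than
coerce; every dropped record is counted in the log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .types import (
    COMPARTMENTS,
    CLASS_FLAGS,
    CellTable,
    CompartmentMap,
    CountMatrix,
    SignatureLibrary,
    SpotGrid,
)

logger = logging.getLogger(__name__)

POSITIONS_FILE = "tissue_positions.csv"
MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
ANNOTATIONS_FILE = "annotations.tsv"
CELLS_FILE = "cells.csv"
SCALEFACTORS_FILE = "scalefactors.json"
TRUTH_FILE = "truth.json"

_FLAGS_TO_CLASS = {flags: name for name, flags in CLASS_FLAGS.items()}


def write_visium_like(
    directory, grid: SpotGrid, counts: CountMatrix, um_per_px: float = 1.0
) -> None:
    """Write a section's grid + counts in the Visium-like layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if list(counts.barcodes) != list(grid.barcodes):
        raise ValueError("grid and count matrix barcodes are not aligned")
    pos = pd.DataFrame(
        {
            "barcode": grid.barcodes,
            "in_tissue": 1,
            "array_row": grid.array_row,
            "array_col": grid.array_col,
            "pxl_x": np.asarray(grid.x_um) / um_per_px,
            "pxl_y": np.asarray(grid.y_um) / um_per_px,
        }
    )
    pos.to_csv(directory / POSITIONS_FILE, index=False, float_format="%.6f")
    coo = counts.values.tocoo()
    sio.mmwrite(directory / MATRIX_FILE, coo.astype(np.int64), field="integer")
    pd.Series(counts.gene_ids).to_csv(
        directory / FEATURES_FILE, sep="\t", index=False, header=False
    )
    pd.Series(counts.barcodes).to_csv(
        directory / BARCODES_FILE, sep="\t", index=False, header=False
    )
    (directory / SCALEFACTORS_FILE).write_text(
        json.dumps(
            {
                "um_per_px": um_per_px,
                "pitch_um": grid.pitch_um,
                "spot_diameter_um": grid.spot_diameter_um,
                "lattice": grid.lattice,
            },
            indent=2,
        )
        + "\n"
    )


def read_visium_like(directory) -> Tuple[SpotGrid, CountMatrix]:
    """Read a section directory; barcodes aligned, in_tissue==0 dropped."""
    directory = Path(directory)
    for fname in (POSITIONS_FILE, MATRIX_FILE, FEATURES_FILE, BARCODES_FILE, SCALEFACTORS_FILE):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {directory}")
    scale = json.loads((directory / SCALEFACTORS_FILE).read_text())
    um_per_px = float(scale["um_per_px"])
    pos = pd.read_csv(directory / POSITIONS_FILE)
    required = ["barcode", "in_tissue", "array_row", "array_col", "pxl_x", "pxl_y"]
    missing = [c for c in required if c not in pos.columns]
    if missing:
        raise ValueError(f"tissue_positions missing column {missing[0]!r}")
    n_out = int((pos["in_tissue"] == 0).sum())
    if n_out:
        logger.info("dropping %d spot(s) with in_tissue == 0", n_out)
        pos = pos[pos["in_tissue"] != 0].reset_index(drop=True)
    genes = pd.read_csv(directory / FEATURES_FILE, sep="\t", header=None)[0].astype(str)
    mat_bcs = pd.read_csv(directory / BARCODES_FILE, sep="\t", header=None)[0].astype(str)
    try:
        mat = sio.mmread(directory / MATRIX_FILE)
    except Exception as exc:  # scipy raises on malformed headers/entries
        raise ValueError(f"malformed Matrix Market file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(mat_bcs)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} features "
            f"x {len(mat_bcs)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("count matrix has negative entries")
    pos_set = set(pos["barcode"].astype(str))
    mat_set = set(mat_bcs)
    for b in pos["barcode"].astype(str):
        if b not in mat_set:
            raise ValueError(f"barcode {b!r} in tissue_positions but not in barcodes.tsv")
    # subset matrix columns to in-tissue spots, in positions order
    col_of = {b: i for i, b in enumerate(mat_bcs)}
    keep = [col_of[b] for b in pos["barcode"].astype(str)]
    csr = sp.csr_matrix(mat)[:, keep]
    n_dropped = len(mat_bcs) - len(keep)
    if n_dropped:
        logger.info("dropping %d matrix column(s) not in tissue positions", n_dropped)
    grid = SpotGrid(
        barcodes=pos["barcode"].astype(str).to_numpy(dtype=object),
        array_row=pos["array_row"].to_numpy(dtype=int),
        array_col=pos["array_col"].to_numpy(dtype=int),
        x_um=pos["pxl_x"].to_numpy(dtype=float) * um_per_px,
        y_um=pos["pxl_y"].to_numpy(dtype=float) * um_per_px,
        lattice=scale["lattice"],
        pitch_um=float(scale["pitch_um"]),
        spot_diameter_um=float(scale["spot_diameter_um"]),
    )
    counts = CountMatrix(
        gene_ids=genes.to_numpy(dtype=object),
        barcodes=grid.barcodes,
        values=csr,
    )
    return grid, counts


def write_annotations(path, comp: CompartmentMap) -> None:
    df = comp.frame.reset_index()
    df.columns = ["barcode", "compartment", "zone"]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotations(path, grid: SpotGrid) -> CompartmentMap:
    """Per-spot compartment labels; must cover the grid exactly."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    for col in ("barcode", "compartment"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col!r}")
    if "zone" not in df.columns:
        df["zone"] = pd.NA
    df["zone"] = df["zone"].where(df["zone"].notna() & (df["zone"] != ""), pd.NA)
    frame = df.set_index("barcode")[["compartment", "zone"]]
    comp = CompartmentMap(frame)
    comp.check_covers(grid)
    return comp


def write_cells(path, cells: CellTable) -> None:
    df = cells.frame.copy()
    df["class"] = cells.class_labels().to_numpy()
    df[["cell_id", "x_um", "y_um", "class"]].to_csv(
        path, index=False, float_format="%.6f"
    )


def read_cells(path) -> CellTable:
    df = pd.read_csv(path, dtype={"cell_id": str, "class": str})
    for col in ("cell_id", "x_um", "y_um", "class"):
        if col not in df.columns:
            raise ValueError(f"cells file missing column {col!r}")
    bad = set(df["class"]) - set(CLASS_FLAGS)
    if bad:
        raise ValueError(
            f"unknown cell class {sorted(bad)[0]!r}; allowed: {sorted(CLASS_FLAGS)}"
        )
    flags = df["class"].map(CLASS_FLAGS)
    df["CD44_pos"] = [f[0] for f in flags]
    df["PTN_pos"] = [f[1] for f in flags]
    return CellTable(df[["cell_id", "x_um", "y_um", "CD44_pos", "PTN_pos"]])


def write_signatures(path, library: SignatureLibrary) -> None:
    rows = [
        {"signature": name, "gene": g} for name in library.names() for g in library[name]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_signatures(path, case_insensitive: bool = False) -> SignatureLibrary:
    """Long-format TSV (signature, gene) -> named gene sets.

    Gene identity is by symbol string, case-sensitive by default; the
    optional flag upper-cases symbols for matching across naming styles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("signature", "gene"):
        if col not in df.columns:
            raise ValueError(f"signature file missing column {col!r}")
    if df["gene"].isna().any() or (df["gene"].str.strip() == "").any():
        raise ValueError("signature file has an empty gene entry")
    if df.empty:
        raise ValueError("signature file is empty")
    sets: dict = {}
    for name, sub in df.groupby("signature", sort=True):
        genes = sub["gene"].str.strip()
        if case_insensitive:
            genes = genes.str.upper()
        sets[name] = tuple(dict.fromkeys(genes))
    return SignatureLibrary(sets)


def write_distances(path, fields) -> None:
    """distances.tsv with columns subject_id, region_id, distance_um."""
    frames = [f.to_frame() for f in fields]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_profile(path, profile) -> None:
    profile.to_frame().to_csv(path, index=False, float_format="%.8f")


def write_niches(path, calls, section_id: Optional[str] = None) -> None:
    rows = []
    for call in calls:
        for b in call.member_barcodes:
            rows.append(
                {
                    "section": section_id or call.section_id,
                    "marker": call.marker,
                    "barcode": b,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_overlap(path, summary) -> None:
    payload = {
        "markers": list(summary.markers),
        "exact_region_counts": {
            "+".join(key): count for key, count in sorted(summary.exact_region_counts.items())
        },
        "jaccard": summary.jaccard.round(6).to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_json(path, payload: Mapping) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
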